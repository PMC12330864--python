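"""Synthetic multichannel EEG, symbolic ground truth and pose tracks.

Every downstream stage of the pipeline is exercised against data whose
generating process is known exactly:

* ``gen_iid_gaussian`` — temporally independent multivariate noise, the
  analytic limit in which the extremal index (dynamics fluidity) is 1;
* ``gen_var1`` — a first-order autoregressive process whose persistence
  knob moves fluidity monotonically;
* ``gen_microstate_hmm`` — a hidden Markov chain over quasi-orthogonal
  channel topographies, the ground truth for microstate segmentation;
* ``gen_pose_track`` — an open-field walk with a rigid 8-point skeleton,
  rendered through a known camera offset/rotation/scale so that arena
  normalization can be tested against ground truth;
* ``gen_cohort`` — groups of AR(1) subjects with a designed persistence
  gap, the end-to-end input for the bootstrap group comparison.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import BODY_PARTS, UNIT_CORNERS, PoseTrack
from .core import InvalidArgument, MultichannelSeries

DEFAULT_RATE = 25.0  # Hz, the coarse-grained trajectory rate

#: Rigid skeleton in egocentric coordinates (animal facing +y, barycenter
#: at the origin = mean of neck and body_mid), arena units.
_SKELETON = {
    "nose": (0.0, 0.085),
    "ear_left": (-0.02, 0.055),
    "ear_right": (0.02, 0.055),
    "neck": (0.0, 0.03),
    "body_mid": (0.0, -0.03),
    "tail_base": (0.0, -0.07),
    "tail_mid": (0.0, -0.11),
    "tail_end": (0.0, -0.15),
}


@dataclass
class SyntheticEEG:
    """A generated multichannel series with optional symbolic ground truth."""

    series: MultichannelSeries
    true_labels: np.ndarray | None = None
    true_templates: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.series.n_channels < 1 or self.series.n_samples < 100:
            raise InvalidArgument("synthetic series needs >=1 channel, >=100 samples")
        if self.true_labels is not None:
            if len(self.true_labels) != self.series.n_samples:
                raise InvalidArgument("true_labels length must match series")
            if self.true_templates is not None and self.true_labels.max() >= len(
                self.true_templates
            ):
                raise InvalidArgument("label index exceeds template count")


@dataclass
class SyntheticCohort:
    """Subjects drawn with identical parameters except a designed group gap."""

    subjects: list[SyntheticEEG]
    group: list[str]
    design: dict
    seed: int


def gen_iid_gaussian(
    n_channels: int, n_samples: int, seed: int, rate: float = DEFAULT_RATE
) -> SyntheticEEG:
    """Independent standard-normal samples on every channel.

    Temporal independence makes threshold exceedances of the log-distance
    observable Poisson, so the estimated extremal index should approach 1.
    """
    if n_channels < 1 or n_samples < 100:
        raise InvalidArgument("n_channels >= 1 and n_samples >= 100 required")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_channels, n_samples))
    params = {"generator": "iid_gaussian", "seed": seed}
    return SyntheticEEG(
        series=MultichannelSeries(values=values, rate=rate, meta=dict(params)),
        params=params,
    )


def gen_var1(
    n_channels: int,
    n_samples: int,
    persistence: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    burn_in: int = 1000,
) -> SyntheticEEG:
    """Channel-wise AR(1): ``x[t+1] = persistence * x[t] + eps``.

    The first ``burn_in`` samples are discarded to remove the
    initial-condition transient; the stationary variance is
    ``noise_sd**2 / (1 - persistence**2)``.
    """
    if not 0 <= persistence < 1:
        raise InvalidArgument("persistence must lie in [0, 1) for stationarity")
    if noise_sd <= 0:
        raise InvalidArgument("noise_sd must be positive")
    if n_channels < 1 or n_samples < 100:
        raise InvalidArgument("n_channels >= 1 and n_samples >= 100 required")
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    eps = rng.standard_normal((n_channels, total)) * noise_sd
    if persistence == 0:
        values = eps
    else:
        from scipy.signal import lfilter

        values = lfilter([1.0], [1.0, -persistence], eps, axis=1)
    values = values[:, burn_in:]
    params = {
        "generator": "var1",
        "persistence": persistence,
        "noise_sd": noise_sd,
        "seed": seed,
        "burn_in": burn_in,
    }
    return SyntheticEEG(
        series=MultichannelSeries(values=values, rate=rate, meta=dict(params)),
        params=params,
    )


def gen_microstate_hmm(
    K: int,
    n_channels: int,
    n_samples: int,
    mean_dwell: float,
    noise_sd: float,
    seed: int,
    amplitude: float = 1.0,
    rate: float = DEFAULT_RATE,
    max_template_corr: float = 0.7,
) -> SyntheticEEG:
    """Markov-switching topography process with known labels and templates.

    The hidden state is a K-state Markov chain with stay probability
    ``1 - 1/mean_dwell`` (geometric dwell of mean ``mean_dwell``) and
    uniform switching among the other states. Templates are random
    unit-norm channel vectors redrawn until every pair has
    ``|Pearson r| < max_template_corr``, guaranteeing identifiable
    clusters. Observation: ``template[state] * amplitude + noise``.
    """
    if K < 2:
        raise InvalidArgument("K must be >= 2")
    if K > n_channels:
        raise InvalidArgument("K > n_channels: templates cannot be quasi-orthogonal")
    if mean_dwell < 1:
        raise InvalidArgument("mean_dwell must be >= 1 sample")
    if n_samples < 100:
        raise InvalidArgument("n_samples >= 100 required")
    rng = np.random.default_rng(seed)

    templates = _draw_templates(rng, K, n_channels, max_template_corr)

    stay = 1.0 - 1.0 / mean_dwell
    switch = (1.0 - stay) / (K - 1)
    labels = np.empty(n_samples, dtype=np.int64)
    labels[0] = rng.integers(K)
    u = rng.random(n_samples)
    jumps = rng.integers(1, K, size=n_samples)  # offset to another state
    for t in range(1, n_samples):
        if u[t] < stay:
            labels[t] = labels[t - 1]
        else:
            labels[t] = (labels[t - 1] + jumps[t]) % K
    values = templates[labels].T * amplitude
    values = values + rng.standard_normal(values.shape) * noise_sd
    params = {
        "generator": "microstate_hmm",
        "K": K,
        "mean_dwell": mean_dwell,
        "noise_sd": noise_sd,
        "amplitude": amplitude,
        "seed": seed,
        "max_template_corr": max_template_corr,
        "stay_probability": stay,
    }
    return SyntheticEEG(
        series=MultichannelSeries(values=values, rate=rate, meta=dict(params)),
        true_labels=labels,
        true_templates=templates,
        params=params,
    )


def _draw_templates(rng, K, n_channels, max_corr, max_tries=1000):
    for _ in range(max_tries):
        t = rng.standard_normal((K, n_channels))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        centered = t - t.mean(axis=1, keepdims=True)
        centered /= np.linalg.norm(centered, axis=1, keepdims=True)
        r = centered @ centered.T
        np.fill_diagonal(r, 0.0)
        if np.max(np.abs(r)) < max_corr:
            return t
    raise InvalidArgument(
        f"could not draw {K} templates with pairwise |r| < {max_corr} "
        f"in {n_channels} channels"
    )


def gen_pose_track(
    n_frames: int,
    fps: float = 25.0,
    camera_offset=(0.0, 0.0),
    camera_angle: float = 0.0,
    arena_size_px: float = 1.0,
    seed: int = 0,
    step_sd: float = 0.01,
    turn_sd: float = 0.2,
) -> PoseTrack:
    """Open-field walk with a rigid skeleton under a known camera transform.

    The barycenter performs a smoothed random walk inside the unit arena
    (reflected at the walls), the skeleton is attached in egocentric
    coordinates with a smoothly drifting heading, and the whole scene is
    rendered to camera pixels by rotating by ``camera_angle``, scaling by
    ``arena_size_px`` and translating by ``camera_offset``. Because the
    camera transform is the exact inverse of arena normalization, the
    normalized track equals the generated ground truth.
    """
    if n_frames < 2:
        raise InvalidArgument("n_frames must be >= 2")
    if arena_size_px <= 0:
        raise InvalidArgument("arena_size_px must be positive")
    rng = np.random.default_rng(seed)

    # smoothed random walk of the barycenter, reflected into [0.2, 0.8]
    steps = rng.standard_normal((n_frames, 2)) * step_sd
    if n_frames > 4:
        kernel = np.ones(5) / 5.0
        steps = np.apply_along_axis(lambda s: np.convolve(s, kernel, "same"), 0, steps)
    bc = 0.5 + np.cumsum(steps, axis=0)
    # triangular reflection map keeping the walk inside [0.2, 0.8]
    bc = 0.8 - np.abs((bc - 0.2) % 1.2 - 0.6)

    heading = np.pi / 2 + np.cumsum(rng.standard_normal(n_frames) * turn_sd)

    points: dict[str, np.ndarray] = {}
    for part in BODY_PARTS:
        ex, ey = _SKELETON[part]
        z = (ex + 1j * ey) * np.exp(1j * (heading - np.pi / 2))
        points[part] = bc + np.column_stack([z.real, z.imag])

    rot = np.array(
        [
            [np.cos(camera_angle), -np.sin(camera_angle)],
            [np.sin(camera_angle), np.cos(camera_angle)],
        ]
    )
    offset = np.asarray(camera_offset, dtype=float)

    def to_camera(xy):
        return (xy @ rot.T) * arena_size_px + offset

    cam_points = {k: to_camera(v) for k, v in points.items()}
    corners = to_camera(UNIT_CORNERS)
    likelihoods = {k: np.full(n_frames, 0.99) for k in cam_points}
    return PoseTrack(
        points=cam_points,
        corners=corners,
        fps=fps,
        likelihoods=likelihoods,
        meta={
            "generator": "pose_track",
            "seed": seed,
            "camera_angle": camera_angle,
            "camera_offset": tuple(offset),
            "arena_size_px": arena_size_px,
            "step_sd": step_sd,
            "ground_truth": {k: v for k, v in points.items()},
        },
    )


def gen_cohort(
    n_per_group: int,
    persistence_by_group: tuple[float, float],
    n_channels: int,
    n_samples: int,
    seed: int,
    group_labels: tuple[str, str] = ("A", "B"),
    noise_sd: float = 1.0,
    rate: float = DEFAULT_RATE,
) -> SyntheticCohort:
    """Two groups of AR(1) subjects differing only in designed persistence.

    Subject seeds are ``seed + subject_index`` so each subject is
    reproducible individually and no two subjects share a stream.
    """
    if n_per_group < 2:
        raise InvalidArgument("need at least 2 subjects per group")
    if group_labels[0] == group_labels[1]:
        raise InvalidArgument("group labels must differ")
    subjects: list[SyntheticEEG] = []
    groups: list[str] = []
    idx = 0
    for label, persistence in zip(group_labels, persistence_by_group):
        for _ in range(n_per_group):
            subjects.append(
                gen_var1(
                    n_channels,
                    n_samples,
                    persistence=persistence,
                    noise_sd=noise_sd,
                    seed=seed + idx,
                    rate=rate,
                )
            )
            groups.append(label)
            idx += 1
    design = {
        "persistence_by_group": dict(zip(group_labels, persistence_by_group)),
        "n_per_group": n_per_group,
        "n_channels": n_channels,
        "n_samples": n_samples,
        "noise_sd": noise_sd,
    }
    return SyntheticCohort(subjects=subjects, group=groups, design=design, seed=seed)
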