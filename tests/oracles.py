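"""Independent oracles shared across test modules."""

import numpy as np
from scipy.optimize import minimize_scalar


def suveges_numeric(gaps, p, use_t_gaps=False):
    """Numerically maximize the Süveges log-likelihood of the extremal index.

    Independent of the closed-form estimator under test: the likelihood
    ``(N - Nc) log(1-theta) + 2 Nc log(theta) - theta p sum(S)`` is
    maximized by bounded scalar search.
    """
    T = np.asarray(gaps, dtype=float)
    S = T if use_t_gaps else T - 1.0
    n = S.size
    nc = int((S > 0).sum())
    s_sum = p * S.sum()
    if s_sum == 0:
        return 0.0

    def nll(theta):
        return -(
            (n - nc) * np.log1p(-theta) + 2 * nc * np.log(theta) - theta * s_sum
        )

    res = minimize_scalar(
        nll, bounds=(1e-12, 1 - 1e-12), method="bounded", options={"xatol": 1e-12}
    )
    return float(res.x)
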