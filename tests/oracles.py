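"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the JZS Bayes factor
is estimated by Monte-Carlo integration over the Cauchy effect-size
prior (averaging noncentral-t densities), not by quadrature, and the
directional sign mass is estimated by importance weighting the same
prior draws.
"""

import math

import numpy as np
from scipy import stats


def mc_jzs_bf(
    t: float, df: float, n_eff: float, r: float, n_draws: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo JZS BF10 and its standard error.

    BF10 = E_delta[nct(t; df, delta*sqrt(N))] / t(t; df) with
    delta ~ Cauchy(0, r).
    """
    rng = np.random.default_rng(seed)
    delta = stats.cauchy.rvs(scale=r, size=n_draws, random_state=rng)
    w = stats.nct.pdf(t, df, delta * math.sqrt(n_eff))
    m0 = stats.t.pdf(t, df)
    bf = float(w.mean() / m0)
    se = float(w.std(ddof=1) / math.sqrt(n_draws) / m0)
    return bf, se


def mc_sign_mass(
    t: float, df: float, n_eff: float, r: float, n_draws: int, seed: int
) -> float:
    """Posterior P(delta > 0 | data) by importance weighting prior draws."""
    rng = np.random.default_rng(seed)
    delta = stats.cauchy.rvs(scale=r, size=n_draws, random_state=rng)
    w = stats.nct.pdf(t, df, delta * math.sqrt(n_eff))
    return float(w[delta > 0].sum() / w.sum())


def direct_update(p0: float, bf: float) -> float:
    """Posterior by direct arithmetic, independent of the library types."""
    odds = p0 / (1.0 - p0) * bf
    return odds / (1.0 + odds)
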