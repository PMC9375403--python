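"""Treatment-group comparison methods for the trial sample.

Two pathways, matching how random-effect Rasch analyses are used as trial
endpoints:

* ``wald_gamma`` -- the treatment effect is the model's group coefficient
  gamma-hat; its nullity is tested with a Wald z-statistic against the
  standard normal (conventional for MML estimates).
* ``ttest_eap`` -- each patient's latent trait is first estimated by EAP and
  the arms are compared with a two-sample Student t-test (pooled variance;
  arms are equal-sized by design.  Welch available behind a flag).

Effects are always reported as treated minus placebo on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import EAPResult, FitResult

__all__ = ["ComparisonResult", "wald_group_test", "ttest_eap"]


@dataclass(frozen=True)
class ComparisonResult:
    method: str  # "wald_gamma" | "ttest_eap"
    effect: float
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def wald_group_test(fit: FitResult) -> ComparisonResult:
    """Wald test of gamma = 0 from a group-covariate fit."""
    if fit.gamma_hat is None:
        raise ValueError("fit has no group covariate")
    if fit.se_gamma is None or not np.isfinite(fit.se_gamma) or fit.se_gamma <= 0:
        raise ValueError("fit has no usable SE for gamma")
    z = fit.gamma_hat / fit.se_gamma
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult("wald_gamma", effect=fit.gamma_hat, statistic=z, p_value=p)


def ttest_eap(eap: EAPResult, group: np.ndarray, welch: bool = False) -> ComparisonResult:
    """Two-sample t-test on EAP latent trait estimates between arms.

    ``effect`` is mean(theta_hat | g=1) - mean(theta_hat | g=0) and the
    statistic is effect / SE, so its sign follows the effect.
    """
    group = np.asarray(group)
    a = np.asarray(eap.theta_hat)[group == 1]
    b = np.asarray(eap.theta_hat)[group == 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    effect = float(a.mean() - b.mean())
    n1, n0 = a.size, b.size
    if welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(
            "ttest_eap", effect=effect, statistic=float(res.statistic),
            p_value=float(res.pvalue), df=float(res.df),
        )
    df = n0 + n1 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n0 - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if effect == 0.0:
            return ComparisonResult("ttest_eap", effect=0.0, statistic=0.0, p_value=1.0, df=float(df))
        t = np.inf if effect > 0 else -np.inf
        return ComparisonResult("ttest_eap", effect=effect, statistic=t, p_value=0.0, df=float(df))
    t = effect / np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult("ttest_eap", effect=effect, statistic=float(t), p_value=float(p), df=float(df))
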