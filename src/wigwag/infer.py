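"""Distribution fitting and hypothesis tests.

Wigwag turn angles are fit with a normal distribution and wigwag
intervals with a lognormal, both by maximum likelihood.  The scale
estimates use the 1/n (maximum-likelihood) form, not the unbiased
1/(n-1) form.  The test helpers are thin contracts over scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence, Tuple

import numpy as np
from scipy import stats


class Family(str, Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"


@dataclass(frozen=True)
class FitResult:
    """MLE parameters of a normal or lognormal fit.

    For the lognormal family, ``location`` and ``scale`` are the
    log-space mean and SD (the normal MLE of the log sample), and the
    log-likelihood is that of the lognormal density in original units.
    """

    family: Family
    location: float
    scale: float
    n: int
    log_likelihood: float

    def stderr_location(self) -> float:
        return self.scale / math.sqrt(self.n)

    def stderr_scale(self) -> float:
        return self.scale / math.sqrt(2 * self.n)


def fit_normal_mle(samples: Sequence[float]) -> FitResult:
    """Normal MLE: location = sample mean, scale = 1/n standard deviation."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample of size >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("degenerate fit: sample has zero variance")
    ll = float(stats.norm.logpdf(x, loc=mu, scale=sigma).sum())
    return FitResult(Family.NORMAL, location=mu, scale=sigma, n=len(x), log_likelihood=ll)


def fit_lognormal_mle(samples: Sequence[float]) -> FitResult:
    """Lognormal MLE: the normal MLE of the log-transformed sample."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample of size >= 2")
    if np.any(x <= 0):
        raise ValueError("lognormal fit requires strictly positive samples")
    base = fit_normal_mle(np.log(x))
    ll = base.log_likelihood - float(np.log(x).sum())
    return FitResult(
        Family.LOGNORMAL,
        location=base.location,
        scale=base.scale,
        n=base.n,
        log_likelihood=ll,
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D = sup |ECDF_a - ECDF_b|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


class PreferenceTests(NamedTuple):
    wilcoxon_stat: float
    wilcoxon_p: float
    chi2_stat: float
    chi2_p: float


def preference_tests(
    per_animal_results: Sequence[Tuple[float, float]],
    region_counts: Tuple[int, int],
) -> PreferenceTests:
    """The study's two preference tests.

    Wilcoxon signed-rank on paired (wall_index, central_index) values,
    one-sided for wall > central (exact distribution when sample size
    permits), and a chi-square goodness-of-fit of the wall-vs-central
    animal counts against the 50/50 split implied by the equal-area
    region construction.
    """
    pairs = np.asarray(per_animal_results, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 5:
        raise ValueError("need >= 5 (wall_index, central_index) pairs")
    diffs = pairs[:, 0] - pairs[:, 1]
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero; Wilcoxon undefined")
    w = stats.wilcoxon(diffs, alternative="greater")

    n_wall, n_central = region_counts
    total = n_wall + n_central
    if total <= 0:
        raise ValueError("region counts must sum to a positive total")
    chi2 = stats.chisquare([n_wall, n_central], f_exp=[total / 2, total / 2])
    return PreferenceTests(
        wilcoxon_stat=float(w.statistic),
        wilcoxon_p=float(w.pvalue),
        chi2_stat=float(chi2.statistic),
        chi2_p=float(chi2.pvalue),
    )


def ttest_ind(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Student's t-test for two independent groups (equal variances)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def anova_oneway(*groups: Sequence[float]) -> Tuple[float, float]:
    """One-way ANOVA across groups."""
    res = stats.f_oneway(*(np.asarray(g, float) for g in groups))
    return float(res.statistic), float(res.pvalue)
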