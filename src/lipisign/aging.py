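"""Per-tissue linear age regressions and slope-heterogeneity testing.

Each tissue gets an ordinary least-squares fit of beta on age; whether the
aging rate differs across tissues is tested with a Cochran-style Q
statistic on the fitted slopes (inverse-variance weights), and a small rule
set classifies each probe's cross-tissue pattern as a consistent decline,
consistent gain, heterogeneous, or flat.  This per-tissue-fit + Q approach
is self-contained and testable; a pooled age-by-tissue dummy-interaction
model is an equivalent alternative (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MammalDataset

__all__ = [
    "AgeTrend",
    "fit_age_regression",
    "fit_tissue_trends",
    "slope_heterogeneity",
    "classify_trend_pattern",
    "trends_table",
]

#: |slope| below this (beta units per age unit) counts as no trend
FLAT_EPS = 1e-4
#: heterogeneity-test significance level used by the pattern classifier
ALPHA_HET = 0.05


@dataclass(frozen=True)
class AgeTrend:
    probe: str
    tissue: str
    slope: float        # beta units per age unit
    intercept: float
    r: float
    n: int
    se: float           # analytic standard error of the slope
    flag: str = ""


def fit_age_regression(ages, betas, probe: str = "", tissue: str = "",
                       min_n: int = 10) -> AgeTrend:
    """OLS fit of beta on age for one tissue.

    Constant beta yields slope 0 with the correlation flagged; constant age
    is an error (no regression is possible).
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(betas, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} samples, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant age: regression undefined")
    flag = ""
    if np.ptp(y) == 0:
        return AgeTrend(probe, tissue, 0.0, float(y[0]), np.nan, len(x), 0.0,
                        flag="constant_beta")
    fit = stats.linregress(x, y)
    return AgeTrend(probe, tissue, float(fit.slope), float(fit.intercept),
                    float(fit.rvalue), len(x), float(fit.stderr), flag=flag)


def fit_tissue_trends(ds: MammalDataset, probe: str, species=None,
                      min_n: int = 10) -> list[AgeTrend]:
    """One age regression per tissue for a probe, pooling species by default.

    ``species`` restricts to a species subset (e.g. a single species so
    that age units are homogeneous within each fit).
    """
    sheet = ds.samples
    if species is not None:
        if isinstance(species, str):
            species = [species]
        sheet = sheet[sheet["species"].isin(list(species))]
    trends = []
    for tissue in sorted(sheet["tissue"].unique()):
        ids = list(sheet.index[sheet["tissue"] == tissue])
        ages = sheet.loc[ids, "age"].to_numpy(dtype=float)
        betas = ds.betas.loc[probe, ids].to_numpy(dtype=float)
        try:
            trends.append(fit_age_regression(ages, betas, probe=probe, tissue=tissue,
                                             min_n=min_n))
        except ValueError:
            continue
    return trends


def _usable(trends) -> list[AgeTrend]:
    return [t for t in trends if t.flag == "" and np.isfinite(t.se) and t.se > 0]


def slope_heterogeneity(trends) -> tuple[float, float]:
    """Cochran Q test for equality of per-tissue slopes.

    Q = sum_i w_i (b_i - b_w)^2 with w_i = 1/SE_i^2 and b_w the
    inverse-variance weighted mean slope; p from chi-square on k-1 df.
    """
    use = _usable(trends)
    if len(use) < 2:
        raise ValueError(f"need at least 2 tissues with valid trends, have {len(use)}")
    b = np.array([t.slope for t in use])
    w = np.array([1.0 / t.se**2 for t in use])
    b_w = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_w) ** 2))
    p = float(stats.chi2.sf(q, len(use) - 1))
    return q, p


def classify_trend_pattern(trends, eps: float = FLAT_EPS,
                           alpha_het: float = ALPHA_HET) -> str:
    """Label a probe's cross-tissue aging pattern.

    flat: every |slope| <= eps.  heterogeneous: non-flat slopes disagree in
    sign, or the Q test rejects slope equality at ``alpha_het``.  Otherwise
    consistent-decline / consistent-gain by the shared sign.
    """
    if not trends:
        raise ValueError("no trends to classify")
    slopes = np.array([t.slope for t in trends])
    nonflat = slopes[np.abs(slopes) > eps]
    if nonflat.size == 0:
        return "flat"
    signs = set(np.sign(nonflat))
    if len(signs) > 1:
        return "heterogeneous"
    use = _usable(trends)
    if len(use) >= 2:
        _, p = slope_heterogeneity(trends)
        if p < alpha_het:
            return "heterogeneous"
    return "consistent-decline" if nonflat[0] < 0 else "consistent-gain"


def trends_table(ds: MammalDataset, probes, species=None, min_n: int = 10
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(probe, tissue) trend rows plus a per-probe (Q, p, pattern) summary."""
    rows = []
    summary = []
    for probe in probes:
        trends = fit_tissue_trends(ds, probe, species=species, min_n=min_n)
        for t in trends:
            rows.append(t.__dict__)
        if len(_usable(trends)) >= 2:
            q, p = slope_heterogeneity(trends)
        else:
            q, p = np.nan, np.nan
        pattern = classify_trend_pattern(trends) if trends else "flat"
        summary.append({"probe": probe, "Q": q, "p": p, "pattern": pattern})
    return pd.DataFrame(rows), pd.DataFrame(summary)
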