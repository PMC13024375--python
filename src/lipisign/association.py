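"""Hybrid Pearson-Spearman (HyPi) association scoring.

For each CpG probe and each lipid marker the four base statistics are the
Pearson and Spearman correlation coefficients and their two-sided p-values.
The hybrid score combines them:

    HyPi = CR_pearson * (-log10 PV_pearson) + CR_spearman * (-log10 PV_spearman)

and a score is *accepted* only when the two coefficients agree in sign, so
the sign of an accepted HyPi equals the sign of the correlations, and its
magnitude grows with both coefficient size and significance.

Conventions (the underlying statistic leaves these open):

* p-values are floored at ``P_MIN = 1e-300`` before taking log10, so a
  machine-zero p cannot produce an infinite score;
* both coefficients exactly zero counts as concordant with score 0; a
  single zero coefficient is non-concordant;
* missing betas are handled pairwise-complete per probe; results with
  fewer than ``min_n`` complete pairs are flagged, not dropped;
* the Spearman p-value uses the t approximation at every n (standard at
  cohort sample sizes); an exact permutation p for n <= 8 is provided as
  :func:`exact_spearman_p`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import LIPIDS, CohortDataset

__all__ = [
    "P_MIN",
    "CorrelationResult",
    "HyPiRecord",
    "pearson",
    "spearman",
    "exact_spearman_p",
    "correlate",
    "hypi_from_stats",
    "hypi",
    "score_cohort",
    "intersect_cohorts",
    "select_extremes",
    "top_probes",
]

P_MIN = 1e-300


@dataclass(frozen=True)
class CorrelationResult:
    cr_pearson: float
    pv_pearson: float
    cr_spearman: float
    pv_spearman: float
    n_used: int
    ok: bool = True
    flag: str = ""


@dataclass(frozen=True)
class HyPiRecord:
    probe: str
    lipid: str
    sex: str
    hypi: float  # NaN when not concordant
    concordant: bool


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df, floored at P_MIN."""
    if abs(r) >= 1.0:
        return P_MIN
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(min(max(p, P_MIN), 1.0))


def _pearson_core(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        return math.nan
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    # exact collinearity lands a few ulp short of +-1; snap so p hits the floor
    if abs(r) > 1.0 - 1e-13:
        r = math.copysign(1.0, r)
    return r


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with two-sided t-distribution p-value.

    Pairwise-complete; raises on fewer than 3 complete pairs or a constant
    vector (callers flag and exclude such probes).
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    r = _pearson_core(xv, yv)
    if math.isnan(r):
        raise ValueError("constant vector: correlation undefined")
    return r, _t_pvalue(r, n), n


def spearman(x, y, p_method: str = "approx") -> tuple[float, float, int]:
    """Spearman rho (midranks for ties) with a t-approximation p-value.

    ``p_method="exact"`` switches to full permutation enumeration (n <= 8).
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = _pearson_core(rx, ry)
    if math.isnan(rho):
        raise ValueError("constant vector: rank correlation undefined")
    if p_method == "exact":
        return rho, exact_spearman_p(xv, yv), n
    return rho, _t_pvalue(rho, n), n


def exact_spearman_p(x, y) -> float:
    """Exact two-sided permutation p for Spearman rho, n <= 8.

    Enumerates all n! permutations of the y midranks and counts those whose
    |rho| reaches the observed |rho| (within 1e-12, guarding float ties).
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3 or n > 8:
        raise ValueError("exact permutation p supported for 3 <= n <= 8")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    obs = abs(_pearson_core(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        rho = _pearson_core(rx, np.array(perm))
        total += 1
        if abs(rho) >= obs - 1e-12:
            count += 1
    return count / total


def correlate(x, y) -> CorrelationResult:
    """All four base statistics for one probe/lipid pair."""
    try:
        r_p, p_p, n = pearson(x, y)
        r_s, p_s, _ = spearman(x, y)
    except ValueError as exc:
        return CorrelationResult(math.nan, math.nan, math.nan, math.nan, 0, ok=False,
                                 flag=str(exc))
    return CorrelationResult(r_p, p_p, r_s, p_s, n)


def hypi_from_stats(cr_p: float, pv_p: float, cr_s: float, pv_s: float) -> tuple[float, bool]:
    """The hybrid score and its sign-concordance acceptance flag.

    Returns ``(score, concordant)``; the score is NaN when the signs of the
    two coefficients disagree (the record is rejected, not zeroed).
    """
    if any(not math.isfinite(v) for v in (cr_p, pv_p, cr_s, pv_s)):
        raise ValueError("undefined correlation inputs")
    sp = 0 if cr_p == 0 else (1 if cr_p > 0 else -1)
    ss = 0 if cr_s == 0 else (1 if cr_s > 0 else -1)
    if sp == 0 and ss == 0:
        return 0.0, True
    if sp != ss or sp == 0 or ss == 0:
        return math.nan, False
    score = cr_p * (-math.log10(max(pv_p, P_MIN))) + cr_s * (-math.log10(max(pv_s, P_MIN)))
    return score, True


def hypi(cres: CorrelationResult, probe: str = "", lipid: str = "", sex: str = "all") -> HyPiRecord:
    if not cres.ok:
        raise ValueError(f"undefined correlation inputs: {cres.flag}")
    score, conc = hypi_from_stats(cres.cr_pearson, cres.pv_pearson,
                                  cres.cr_spearman, cres.pv_spearman)
    return HyPiRecord(probe=probe, lipid=lipid, sex=sex, hypi=score, concordant=conc)


# ---------------------------------------------------------------------------
# Bulk scoring


def _bulk_corr(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Pearson of B (probes x n) against y; returns (r, p, valid)."""
    n = B.shape[1]
    Bc = B - B.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt(np.einsum("ij,ij->i", Bc, Bc))
    sy = math.sqrt(float(yc @ yc))
    valid = (sx > 0) & (sy > 0)
    r = np.full(B.shape[0], np.nan)
    np.divide(Bc @ yc, sx * sy, out=r, where=valid)
    r = np.clip(r, -1.0, 1.0)
    r = np.where(np.abs(r) > 1.0 - 1e-13, np.copysign(1.0, r), r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, P_MIN, p)
    p = np.clip(p, P_MIN, 1.0)
    return r, p, valid


def _bulk_stats(B: np.ndarray, y: np.ndarray):
    """Pearson and Spearman stats for every row of B vs y (no missing values)."""
    n = B.shape[1]
    r_p, p_p, v1 = _bulk_corr(B, y)
    ranks = stats.rankdata(B, axis=1)
    yr = stats.rankdata(y)
    r_s, p_s, v2 = _bulk_corr(ranks, yr)
    valid = v1 & v2
    n_used = np.full(B.shape[0], n)
    return r_p, p_p, r_s, p_s, n_used, valid


def score_cohort(dataset: CohortDataset, sex_strata=("F", "M"), lipids=LIPIDS,
                 min_n: int = 30) -> pd.DataFrame:
    """One HyPi record per (probe, lipid, sex stratum).

    ``sex_strata`` entries are "F", "M" or "all".  Probes failing
    preconditions (constant beta, too few complete pairs) are flagged in the
    output, never silently dropped; ``accepted`` marks records that are
    concordant, unflagged and have ``n_used >= min_n``.
    """
    frames = []
    for sex in sex_strata:
        if sex == "all":
            subj = dataset.samples.index
        else:
            subj = dataset.samples.index[dataset.samples["sex"] == sex]
        if len(subj) == 0:
            raise ValueError(f"empty sex stratum: {sex!r}")
        B = dataset.betas.loc[:, subj].to_numpy(dtype=float)
        has_nan = not np.isfinite(B).all()
        for lipid in lipids:
            y = dataset.samples.loc[subj, lipid].to_numpy(dtype=float)
            if has_nan or not np.isfinite(y).all():
                rows = [correlate(B[i], y) for i in range(B.shape[0])]
                r_p = np.array([c.cr_pearson for c in rows])
                p_p = np.array([c.pv_pearson for c in rows])
                r_s = np.array([c.cr_spearman for c in rows])
                p_s = np.array([c.pv_spearman for c in rows])
                n_used = np.array([c.n_used for c in rows])
                valid = np.array([c.ok for c in rows])
            else:
                r_p, p_p, r_s, p_s, n_used, valid = _bulk_stats(B, y)
            df = pd.DataFrame({
                "probe": dataset.betas.index,
                "lipid": lipid,
                "sex": sex,
                "cr_pearson": r_p, "pv_pearson": p_p,
                "cr_spearman": r_s, "pv_spearman": p_s,
                "n_used": n_used,
            })
            frames.append(df.assign(valid=valid))
    table = pd.concat(frames, ignore_index=True)

    sp = np.sign(table["cr_pearson"])
    ss = np.sign(table["cr_spearman"])
    both_zero = (sp == 0) & (ss == 0)
    concordant = ((sp == ss) & (sp != 0)) | both_zero
    score = (
        table["cr_pearson"] * (-np.log10(np.clip(table["pv_pearson"], P_MIN, 1.0)))
        + table["cr_spearman"] * (-np.log10(np.clip(table["pv_spearman"], P_MIN, 1.0)))
    )
    table["hypi"] = np.where(concordant & table["valid"], np.where(both_zero, 0.0, score), np.nan)
    table["concordant"] = concordant & table["valid"]
    table["flag"] = np.where(~table["valid"], "undefined",
                             np.where(table["n_used"] < min_n, "low_n", ""))
    table["accepted"] = table["concordant"] & (table["flag"] == "")
    return table.drop(columns=["valid"])


def _select_group(group: pd.DataFrame, k: int | None, threshold: float | None) -> pd.DataFrame:
    acc = group[group["accepted"]]
    if threshold is not None:
        return acc[acc["hypi"].abs() >= threshold]
    # deterministic: rank by |hypi| descending, probe id ascending for ties
    order = acc.assign(_a=acc["hypi"].abs()).sort_values(
        ["_a", "probe"], ascending=[False, True])
    return order.head(k).drop(columns="_a")


def intersect_cohorts(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      k: int | None = 20, threshold: float | None = None) -> pd.DataFrame:
    """Probes passing the selection rule in BOTH cohorts with matching sign.

    Selection runs within each (lipid, sex) group: top-``k`` by absolute
    HyPi among accepted records (ties broken lexicographically by probe id),
    or ``|hypi| >= threshold`` when a threshold is given.  Returns one row
    per surviving (probe, lipid, sex) with the sign and both scores.
    """
    probes_a = set(table_a["probe"])
    probes_b = set(table_b["probe"])
    if not probes_a & probes_b:
        raise ValueError("disjoint probe universes")
    out = []
    keys = sorted(set(map(tuple, table_a[["lipid", "sex"]].drop_duplicates().to_numpy()))
                  & set(map(tuple, table_b[["lipid", "sex"]].drop_duplicates().to_numpy())))
    for lipid, sex in keys:
        ga = table_a[(table_a["lipid"] == lipid) & (table_a["sex"] == sex)]
        gb = table_b[(table_b["lipid"] == lipid) & (table_b["sex"] == sex)]
        sel_a = _select_group(ga, k, threshold).set_index("probe")
        sel_b = _select_group(gb, k, threshold).set_index("probe")
        shared = sorted(set(sel_a.index) & set(sel_b.index))
        for probe in shared:
            ha = float(sel_a.loc[probe, "hypi"])
            hb = float(sel_b.loc[probe, "hypi"])
            if np.sign(ha) == np.sign(hb):
                out.append({"probe": probe, "lipid": lipid, "sex": sex,
                            "sign": int(np.sign(ha)), "hypi_a": ha, "hypi_b": hb})
    return pd.DataFrame(out, columns=["probe", "lipid", "sex", "sign", "hypi_a", "hypi_b"])


def select_extremes(table: pd.DataFrame, k: int = 6) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k probes by signed HyPi among accepted records.

    Ties break lexicographically by probe id; the two lists are disjoint.
    """
    acc = table[table["accepted"]].copy()
    if len(acc) < 2 * k:
        raise ValueError(f"need at least {2 * k} accepted records, have {len(acc)}")
    top = acc.sort_values(["hypi", "probe"], ascending=[False, True]).head(k)
    bottom_pool = acc.loc[~acc.index.isin(top.index)]
    bottom = bottom_pool.sort_values(["hypi", "probe"], ascending=[True, True]).head(k)
    return list(top["probe"]), list(bottom["probe"])


def top_probes(table: pd.DataFrame, k: int) -> list[str]:
    """The k distinct probes with the largest absolute accepted HyPi.

    A probe's score is the maximum |hypi| over its accepted records (across
    lipids and strata); ties break lexicographically.
    """
    acc = table[table["accepted"]].copy()
    acc["_a"] = acc["hypi"].abs()
    best = acc.groupby("probe")["_a"].max().reset_index()
    best = best.sort_values(["_a", "probe"], ascending=[False, True])
    return list(best["probe"].head(k))
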