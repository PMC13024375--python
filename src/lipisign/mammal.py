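"""Projection of human-selected probes onto the pan-mammalian dataset.

Covers the comparative stages that sit between marker selection and the
dendrogram machinery: probe projection onto the mammalian array, the
species/tissue sample-size filters, within-stratum age correlations, the
concordance of human HyPi scores with mammalian age correlations, the
species-level maximum-lifespan association, and a silhouette-based tissue
identity score (a label-purity statistic over the probe-beta space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .association import pearson, spearman
from .datasets import MammalDataset

__all__ = [
    "ProbeProjection",
    "FilterReport",
    "project_probes",
    "filter_samples",
    "age_correlation",
    "hypi_age_concordance",
    "lifespan_association",
    "tissue_identity_score",
]


@dataclass(frozen=True)
class ProbeProjection:
    probes: tuple[str, ...]
    n_human: int
    n_mammal: int

    @property
    def n_retained(self) -> int:
        return len(self.probes)

    @property
    def n_lost(self) -> int:
        return self.n_human - self.n_retained


def project_probes(human_probes, mammal_probes) -> ProbeProjection:
    """Intersect human-selected probes with the mammalian probe universe."""
    hset, mset = set(human_probes), set(mammal_probes)
    if not hset or not mset:
        raise ValueError("empty probe set")
    shared = tuple(sorted(hset & mset))
    if not shared:
        raise ValueError("no shared probes between human selection and mammalian array")
    return ProbeProjection(probes=shared, n_human=len(hset), n_mammal=len(mset))


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_after_species: int
    n_after_tissue: int
    species_kept: tuple[str, ...]
    species_dropped: tuple[str, ...]
    tissues_kept: tuple[str, ...]
    tissues_dropped: tuple[str, ...]


def filter_samples(ds: MammalDataset, min_species_n: int = 200, min_tissue_n: int = 50
                   ) -> tuple[MammalDataset, FilterReport]:
    """Apply the species-then-tissue sample-size filters.

    Species are filtered on their counts in the input; tissue counts are
    then recomputed on the species survivors before the tissue filter is
    applied.  The report makes the sequential semantics auditable.  Note
    that re-applying the filter is only guaranteed to be a no-op when every
    retained species/tissue still meets its threshold after filtering.
    """
    sheet = ds.samples
    sp_counts = sheet["species"].value_counts()
    sp_keep = sorted(sp_counts.index[sp_counts >= min_species_n])
    surv = sheet[sheet["species"].isin(sp_keep)]
    ti_counts = surv["tissue"].value_counts()
    ti_keep = sorted(ti_counts.index[ti_counts >= min_tissue_n])
    final = surv[surv["tissue"].isin(ti_keep)]
    if final.empty:
        raise ValueError(
            f"no samples survive filters (min_species_n={min_species_n}, "
            f"min_tissue_n={min_tissue_n})")
    report = FilterReport(
        n_input=len(sheet),
        n_after_species=len(surv),
        n_after_tissue=len(final),
        species_kept=tuple(sp_keep),
        species_dropped=tuple(sorted(set(sp_counts.index) - set(sp_keep))),
        tissues_kept=tuple(ti_keep),
        tissues_dropped=tuple(sorted(set(ti_counts.index) - set(ti_keep))),
    )
    return ds.subset_samples(list(final.index)), report


def _strata(sheet: pd.DataFrame, stratify_by: str) -> pd.Series:
    if stratify_by == "species":
        return sheet["species"]
    if stratify_by == "tissue":
        return sheet["tissue"]
    if stratify_by in ("species_tissue", "species x tissue"):
        return sheet["species"] + "|" + sheet["tissue"]
    raise ValueError(f"unknown stratification: {stratify_by!r}")


def age_correlation(ds: MammalDataset, probes, stratify_by: str = "species",
                    method: str = "pearson", min_n: int = 10,
                    tissues=None) -> pd.DataFrame:
    """Correlation of beta vs age within each stratum, per probe.

    Ages stay in species-native units; strata never mix species when
    ``stratify_by`` includes species, so units never mix either.  Strata
    with n < ``min_n`` or constant age/beta are flagged, not dropped.
    ``tissues`` optionally restricts to a tissue subset first (e.g. blood
    only).
    """
    if isinstance(probes, str):
        probes = [probes]
    sheet = ds.samples
    if tissues is not None:
        sheet = sheet[sheet["tissue"].isin(list(tissues))]
    labels = _strata(sheet, stratify_by)
    corr = pearson if method == "pearson" else spearman
    rows = []
    for stratum in sorted(labels.unique()):
        ids = list(sheet.index[labels == stratum])
        ages = sheet.loc[ids, "age"].to_numpy(dtype=float)
        for probe in probes:
            beta = ds.betas.loc[probe, ids].to_numpy(dtype=float)
            flag = ""
            r = p = np.nan
            if len(ids) < min_n:
                flag = "low_n"
            else:
                try:
                    r, p, _ = corr(ages, beta)
                except ValueError:
                    flag = "constant"
            rows.append({"stratum": stratum, "probe": probe, "r": r, "p": p,
                         "n": len(ids), "flag": flag})
    return pd.DataFrame(rows)


def hypi_age_concordance(hypi_table: pd.DataFrame, age_corrs: pd.DataFrame
                         ) -> dict[str, dict[str, float]]:
    """Regress mean mammalian age correlation on human HyPi, per sex stratum.

    For each probe the y value is the unweighted mean of its per-stratum
    age-correlation coefficients (flagged strata excluded); the x value is
    the probe's accepted HyPi record with the largest |score| in that sex
    stratum.  Returns per-sex slope/intercept/Pearson r/n of the fitted
    least-squares line.
    """
    valid = age_corrs[(age_corrs["flag"] == "") & np.isfinite(age_corrs["r"])]
    mean_r = valid.groupby("probe")["r"].mean()
    out: dict[str, dict[str, float]] = {}
    for sex in sorted(hypi_table["sex"].unique()):
        sub = hypi_table[(hypi_table["sex"] == sex) & hypi_table["accepted"]].copy()
        sub["_a"] = sub["hypi"].abs()
        best = sub.sort_values(["_a", "probe"], ascending=[False, True]) \
                  .drop_duplicates("probe").set_index("probe")["hypi"]
        shared = sorted(set(best.index) & set(mean_r.index))
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 probes shared for sex stratum {sex!r}")
        x = best.loc[shared].to_numpy(dtype=float)
        y = mean_r.loc[shared].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        out[sex] = {"slope": float(fit.slope), "intercept": float(fit.intercept),
                    "r": float(fit.rvalue), "n": len(shared)}
    return out


def lifespan_association(ds: MammalDataset, probe: str, log_lifespan: bool = True
                         ) -> tuple[float, float, int]:
    """Correlate per-species mean beta with species maximum lifespan.

    One point per species (so per-species sample counts do not weight the
    correlation); lifespan is log-transformed by default.  Requires at
    least 4 species.
    """
    sheet = ds.samples
    species = sorted(sheet["species"].unique())
    if len(species) < 4:
        raise ValueError(f"need at least 4 species, have {len(species)}")
    means = []
    lifespans = []
    for sp in species:
        ids = list(sheet.index[sheet["species"] == sp])
        means.append(float(ds.betas.loc[probe, ids].mean()))
        lifespans.append(float(sheet.loc[ids[0], "max_lifespan"]))
    ls = np.log(lifespans) if log_lifespan else np.array(lifespans)
    r, p, n = pearson(np.array(means), ls)
    return r, p, len(species)


def tissue_identity_score(ds: MammalDataset, probes, label: str = "tissue") -> float:
    """Mean silhouette width of samples in probe-beta space, by label.

    Quantifies how coherently samples group by tissue (or species) identity:
    near 1 for cleanly separated labels, near 0 for labels unrelated to the
    methylation profile.
    """
    if label not in ("tissue", "species"):
        raise ValueError("label must be 'tissue' or 'species'")
    if isinstance(probes, str):
        probes = [probes]
    y = ds.samples[label].to_numpy()
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    if counts.min() < 2:
        raise ValueError("each label needs at least 2 samples")
    X = ds.betas.loc[list(probes)].to_numpy(dtype=float).T
    return float(silhouette_score(X, y, metric="euclidean"))
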