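"""End-to-end orchestration: simulate -> score -> project -> trends -> concordance.

``run_all`` executes the whole pipeline from a single :class:`RunConfig`
(loadable from YAML), writes every intermediate table with a provenance
header, and returns a machine-readable report.  All randomness derives from
the config seed, so an identical config reruns byte-identically.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import config_digest, provenance_header, write_cohort, write_mammal
from .synthetic import (CohortConfig, MammalConfig, SpeciesSpec, TissueSpec,
                        simulate_cohort, simulate_mammalian_dataset,
                        simulate_species_tree)
from . import association, mammal as mammal_mod, aging, concordance

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


_DEFAULT_SPECIES = (
    ("Species_01", 85.0), ("Species_02", 40.0), ("Species_03", 28.0),
    ("Species_04", 22.0), ("Species_05", 12.0), ("Species_06", 6.5),
    ("Species_07", 4.0), ("Species_08", 32.0),
)
_DEFAULT_TISSUES = (
    ("Blood", 18, 0.00, -0.0010),
    ("Liver", 18, 0.04, -0.0015),
    ("Adipose", 18, -0.03, -0.0008),
    ("Muscle", 18, 0.02, 0.0006),
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    The filter defaults mirror the comparative dataset's inclusion rules
    (species with >= 200 samples, tissues with >= 50) and the marker
    selection keeps the top and bottom six probes by HyPi.
    """

    seed: int = 0
    outdir: str = "lipisign_run"
    # cohort simulation
    n_subjects: int = 300
    n_probes: int = 400
    n_true_probes: int = 12
    effect_r: float = 0.3
    nonlinear_fraction: float = 0.25
    cohort_labels: tuple = ("ASAS", "CITY")
    # selection
    sex_strata: tuple = ("all",)
    min_n: int = 30
    k_select: int = 20
    k_extremes: int = 6
    # mammalian simulation
    species: tuple = _DEFAULT_SPECIES
    tissues: tuple = _DEFAULT_TISSUES
    brownian_sigma: float = 0.08
    noise_sd: float = 0.01
    lifespan_effect: float = 0.05
    # filters / analysis
    min_species_n: int = 40
    min_tissue_n: int = 40
    linkage: str = "average"
    reference_tissue: str = "Blood"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("species", "tissues", "cohort_labels", "sex_strata"):
            setattr(cfg, name, tuple(tuple(x) if isinstance(x, list) else x
                                     for x in getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report.

    Report blocks: simulate_cohorts, association, simulate_mammal,
    mammal_analysis, aging_trends, concordance.  Identical config + seed
    produce a byte-identical report (no timestamps).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # the hash covers the scientific parameters, not the output location,
    # so reruns into different directories stay byte-identical
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir", None)
    chash = config_digest(cfg_dict)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": cfg_dict,
        "stages": {},
    }

    # -- stage 1: simulate the two human cohorts ---------------------------
    stage = "simulate_cohorts"
    try:
        ccfg = CohortConfig(
            n_subjects=config.n_subjects, n_probes=config.n_probes,
            n_true_probes=config.n_true_probes, effect_r=config.effect_r,
            nonlinear_fraction=config.nonlinear_fraction, seed=config.seed,
        )
        cohorts = {lab: simulate_cohort(ccfg, lab) for lab in config.cohort_labels}
        for lab, ds in cohorts.items():
            write_cohort(ds, outdir / f"cohort_{lab}", seed=config.seed, config_hash=chash)
        report["stages"][stage] = {
            "cohorts": {lab: {"n_subjects": ds.n_subjects, "n_probes": len(ds.probes)}
                        for lab, ds in cohorts.items()},
            "input_hashes": {lab: _hash_file(outdir / f"cohort_{lab}" / "betas.tsv")
                             for lab in cohorts},
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 2: HyPi scoring, two-cohort intersection, extremes ----------
    stage = "association"
    try:
        tables = {lab: association.score_cohort(ds, sex_strata=config.sex_strata,
                                                min_n=config.min_n)
                  for lab, ds in cohorts.items()}
        for lab, tab in tables.items():
            path = outdir / f"hypi_{lab}.tsv"
            with open(path, "w") as fh:
                fh.write(provenance_header(config.seed, chash) + "\n")
                tab.to_csv(fh, sep="\t", index=False, float_format="%.8g",
                           lineterminator="\n")
        lab_a, lab_b = config.cohort_labels[:2]
        inter = association.intersect_cohorts(tables[lab_a], tables[lab_b],
                                              k=config.k_select)
        selected = sorted(set(inter["probe"]))
        top, bottom = association.select_extremes(tables[lab_a], k=config.k_extremes)
        report["stages"][stage] = {
            "n_records": {lab: len(tab) for lab, tab in tables.items()},
            "n_accepted": {lab: int(tab["accepted"].sum()) for lab, tab in tables.items()},
            "n_intersected": len(selected),
            "selected_probes": selected,
            "extremes_top": top,
            "extremes_bottom": bottom,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 3: simulate the pan-mammalian dataset -----------------------
    stage = "simulate_mammal"
    try:
        tree = simulate_species_tree(len(config.species), seed=config.seed,
                                     labels=[s[0] for s in config.species])
        mcfg = MammalConfig(
            species=tuple(SpeciesSpec(name, float(ls)) for name, ls in config.species),
            tissues=tuple(TissueSpec(name, int(n), float(off), float(slope))
                          for name, n, off, slope in config.tissues),
            brownian_sigma=config.brownian_sigma, noise_sd=config.noise_sd,
            lifespan_effect=config.lifespan_effect, seed=config.seed,
        )
        mam = simulate_mammalian_dataset(tree, mcfg, probes=list(cohorts[lab_a].probes))
        write_mammal(mam, outdir / "mammal", seed=config.seed, config_hash=chash,
                     newick=tree.newick)
        report["stages"][stage] = {
            "n_samples": int(mam.samples.shape[0]),
            "n_species": len(mam.species),
            "n_tissues": len(mam.tissues),
            "clipped_fraction": mam.truth["clipped_fraction"],
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 4: projection, filters, age/lifespan correlations ----------
    stage = "mammal_analysis"
    try:
        proj = mammal_mod.project_probes(selected, mam.probes)
        filtered, frep = mammal_mod.filter_samples(
            mam, min_species_n=config.min_species_n, min_tissue_n=config.min_tissue_n)
        probes_used = list(proj.probes) if proj.probes else selected
        age_corr = mammal_mod.age_correlation(filtered, probes_used,
                                              stratify_by="species")
        with open(outdir / "age_correlations.tsv", "w") as fh:
            fh.write(provenance_header(config.seed, chash) + "\n")
            age_corr.to_csv(fh, sep="\t", index=False, float_format="%.8g",
                            lineterminator="\n")
        life = {}
        for probe in probes_used[: config.k_extremes * 2]:
            r, p, ns = mammal_mod.lifespan_association(filtered, probe)
            life[probe] = {"r": r, "p": p, "n_species": ns}
        sil = mammal_mod.tissue_identity_score(filtered, probes_used, label="tissue")
        report["stages"][stage] = {
            "n_projected": proj.n_retained,
            "n_lost": proj.n_lost,
            "filter": {"n_input": frep.n_input, "n_after_species": frep.n_after_species,
                       "n_after_tissue": frep.n_after_tissue,
                       "species_kept": list(frep.species_kept),
                       "tissues_kept": list(frep.tissues_kept)},
            "lifespan_associations": life,
            "tissue_silhouette": sil,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 5: per-tissue aging trends ----------------------------------
    stage = "aging_trends"
    try:
        trend_rows, trend_summary = aging.trends_table(filtered, probes_used)
        for name, df in (("age_trends.tsv", trend_rows),
                         ("age_trend_summary.tsv", trend_summary)):
            with open(outdir / name, "w") as fh:
                fh.write(provenance_header(config.seed, chash) + "\n")
                df.to_csv(fh, sep="\t", index=False, float_format="%.8g",
                          lineterminator="\n")
        report["stages"][stage] = {
            "n_trends": len(trend_rows),
            "patterns": trend_summary["pattern"].value_counts().to_dict(),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 6: dendrogram concordance -----------------------------------
    stage = "concordance"
    try:
        others = [t for t in filtered.tissues if t != config.reference_tissue]
        conc = concordance.tissue_concordance(
            filtered, probes_used, reference=config.reference_tissue,
            others=others, linkage=config.linkage)
        with open(outdir / "concordance.tsv", "w") as fh:
            fh.write(provenance_header(config.seed, chash) + "\n")
            conc.to_csv(fh, sep="\t", index=False, float_format="%.8g",
                        lineterminator="\n")
        for _, row in conc.iterrows():
            (outdir / f"tree_{row['tissue']}.nwk").write_text(row["newick_tissue"] + "\n")
        (outdir / f"tree_{config.reference_tissue}.nwk").write_text(
            conc.iloc[0]["newick_reference"] + "\n")
        sexres = concordance.sex_concordance(filtered, probes_used,
                                             linkage=config.linkage)
        report["stages"][stage] = {
            "tissue_concordance": conc.drop(
                columns=["newick_reference", "newick_tissue"]).to_dict(orient="records"),
            "sex_concordance": {
                "cophenetic_r": sexres.cophenetic_r,
                "entanglement_before": sexres.entanglement_before,
                "entanglement_after": sexres.entanglement_after,
            },
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                      default=_jsonable) + "\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
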