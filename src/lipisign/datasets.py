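"""Data containers and TSV input/output.

Two dataset shapes flow through the pipeline:

* a human cohort — a sample sheet (subject id, sex, cohort label, three serum
  lipid markers in mg/dL) plus a beta-value matrix (CpG probes x subjects,
  values in [0, 1]);
* a pan-mammalian dataset — a sample sheet (species, tissue, age, sex,
  species maximum lifespan) plus a beta matrix on a shared probe universe.

Beta matrices are plain :class:`pandas.DataFrame` objects with probe ids as
the index and sample ids as columns.  All files are tab-separated text; the
first line of every written file is a ``#``-prefixed provenance header
(tool version, seed, config hash) which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "LIPIDS",
    "CohortDataset",
    "MammalDataset",
    "Diagnostic",
    "read_cohort",
    "write_cohort",
    "read_mammal",
    "write_mammal",
    "validate_inputs",
]

LIPIDS = ("HDL", "TCH", "TGY")

_COHORT_SHEET_COLS = ["sex", "cohort", "HDL", "TCH", "TGY"]
_MAMMAL_SHEET_COLS = ["species", "tissue", "age", "sex", "max_lifespan"]


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"# lipisign {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def config_digest(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class CohortDataset:
    """Sample sheet + beta matrix for one human cohort.

    ``samples`` is indexed by subject id with columns sex / cohort /
    HDL / TCH / TGY; ``betas`` is probes x subjects.  ``truth`` optionally
    carries the planted ground truth of a synthetic cohort.
    """

    samples: pd.DataFrame
    betas: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.samples.index) != list(self.betas.columns):
            raise ValueError("sample sheet subjects and beta matrix columns do not coincide")
        vals = self.betas.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values outside [0, 1]")

    @property
    def probes(self) -> list[str]:
        return list(self.betas.index)

    @property
    def n_subjects(self) -> int:
        return self.samples.shape[0]


@dataclass
class MammalDataset:
    """Sample sheet + beta matrix for the pan-mammalian dataset."""

    samples: pd.DataFrame
    betas: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        if list(self.samples.index) != list(self.betas.columns):
            raise ValueError("sample sheet and beta matrix sample sets do not coincide")
        if (self.samples["age"] < 0).any():
            raise ValueError("negative age in sample sheet")
        if (self.samples["max_lifespan"] <= 0).any():
            raise ValueError("non-positive max_lifespan in sample sheet")

    @property
    def probes(self) -> list[str]:
        return list(self.betas.index)

    @property
    def species(self) -> list[str]:
        return sorted(self.samples["species"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def subset_samples(self, sample_ids: list[str]) -> "MammalDataset":
        return MammalDataset(
            samples=self.samples.loc[sample_ids].copy(),
            betas=self.betas.loc[:, sample_ids].copy(),
            truth=self.truth,
        )


# ---------------------------------------------------------------------------
# TSV round trip


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.8g", lineterminator="\n")


def _read_tsv(path: Path, index_col: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_cohort(ds: CohortDataset, outdir: str | Path, seed: int | None = None,
                 config_hash: str | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(seed, config_hash)
    _write_tsv(ds.samples, outdir / "samples.tsv", header, "subject_id")
    _write_tsv(ds.betas, outdir / "betas.tsv", header, "probe_id")
    if ds.truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(ds.truth.to_dict(orient="records"), fh, indent=1, sort_keys=True)


def read_cohort(indir: str | Path) -> CohortDataset:
    indir = Path(indir)
    samples = _read_tsv(indir / "samples.tsv", "subject_id")
    betas = _read_tsv(indir / "betas.tsv", "probe_id")
    betas.columns = betas.columns.astype(str)
    samples.index = samples.index.astype(str)
    truth = None
    tpath = indir / "truth.json"
    if tpath.exists():
        truth = pd.DataFrame(json.loads(tpath.read_text()))
    return CohortDataset(samples=samples, betas=betas, truth=truth)


def write_mammal(ds: MammalDataset, outdir: str | Path, seed: int | None = None,
                 config_hash: str | None = None, newick: str | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(seed, config_hash)
    _write_tsv(ds.samples, outdir / "samples.tsv", header, "sample_id")
    _write_tsv(ds.betas, outdir / "betas.tsv", header, "probe_id")
    if newick is not None:
        (outdir / "species_tree.nwk").write_text(newick + "\n")


def read_mammal(indir: str | Path) -> MammalDataset:
    indir = Path(indir)
    samples = _read_tsv(indir / "samples.tsv", "sample_id")
    betas = _read_tsv(indir / "betas.tsv", "probe_id")
    betas.columns = betas.columns.astype(str)
    samples.index = samples.index.astype(str)
    return MammalDataset(samples=samples, betas=betas)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "fatal" | "warning"
    message: str


def validate_inputs(sheet_path: str | Path, betas_path: str | Path,
                    kind: str = "cohort") -> list[Diagnostic]:
    """Structural checks on an on-disk dataset before it enters the pipeline.

    Returns a list of diagnostics; callers treat any ``fatal`` entry as a
    hard stop.  Checks: readable TSV, beta range [0,1], sheet/matrix sample
    agreement, duplicate probe ids, missing-value rate.
    """
    out: list[Diagnostic] = []
    index_col = "subject_id" if kind == "cohort" else "sample_id"
    try:
        sheet = _read_tsv(Path(sheet_path), index_col)
        betas = _read_tsv(Path(betas_path), "probe_id")
    except Exception as exc:  # malformed TSV
        return [Diagnostic("fatal", f"malformed TSV: {exc}")]

    vals = betas.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        out.append(Diagnostic(
            "fatal",
            f"beta values outside [0,1]: range [{finite.min():.4g}, {finite.max():.4g}]"))

    sheet_ids = set(map(str, sheet.index))
    mat_ids = set(map(str, betas.columns))
    if mat_ids - sheet_ids:
        out.append(Diagnostic(
            "fatal", f"{len(mat_ids - sheet_ids)} matrix sample(s) absent from sample sheet"))
    if sheet_ids - mat_ids:
        out.append(Diagnostic(
            "fatal", f"{len(sheet_ids - mat_ids)} sheet sample(s) absent from beta matrix"))

    if betas.index.duplicated().any():
        out.append(Diagnostic(
            "fatal", f"{int(betas.index.duplicated().sum())} duplicate probe id(s)"))

    miss = float(np.mean(~np.isfinite(vals))) if vals.size else 0.0
    if miss > 0:
        out.append(Diagnostic("warning", f"missing beta rate {miss:.3%}"))
    return out
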