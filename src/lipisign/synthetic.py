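"""Synthetic human-cohort and pan-mammalian methylation data.

The generator plants exactly the statistical structure the downstream
analysis looks for, so every stage can be verified by parameter recovery:

* human cohorts with a configurable number of "true" CpG probes whose beta
  values are monotone functions of one serum lipid marker (HDL, TCH or TGY),
  with the population correlation calibrated to a target magnitude;
* a random rooted binary species tree (sequential random coalescence);
* a pan-mammalian dataset whose per-probe species baselines evolve by
  Brownian motion along that tree, plus additive tissue offsets,
  tissue-specific linear age slopes, an optional log-lifespan term on a
  subset of probes, and Gaussian residual noise, clipped to [0, 1].

True-probe betas are inverse-logit transforms of a latent
``s * (w*u + sqrt(1-w^2)*eps)`` where ``u`` is the (standardised) lipid
signal — identity link for linear probes and, for the non-linear fraction,
a rank-preserving signed cube root pushed through a steeper sigmoid.  The
cube root compresses the tails and the steep sigmoid saturates them, so
Spearman exceeds Pearson for these probes (a heavy-tailed link such as a
plain cube does the opposite: its outliers inflate the Pearson moment).
The signal weight ``w`` is solved numerically on a fixed large calibration
sample so the population correlation matches ``effect_r``: Pearson for
linear probes, Spearman for non-linear ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .datasets import LIPIDS, CohortDataset, MammalDataset

__all__ = [
    "CohortConfig",
    "SpeciesSpec",
    "TissueSpec",
    "MammalConfig",
    "SpeciesTree",
    "simulate_cohort",
    "simulate_species_tree",
    "simulate_mammalian_dataset",
]

#: latent logit SD for linear probes; keeps betas well inside (0, 1)
_LATENT_SCALE = 0.8
#: steeper logit scale for non-linear probes (saturating, bimodal-ish betas)
_LATENT_SCALE_NONLINEAR = 4.0
#: SD of sign(z)|z|^(1/3) for standard normal z: sqrt(2^(1/3) G(5/6) / sqrt(pi))
_CUBEROOT_SD = 0.8957566

_DEFAULT_LIPID_MEANS = {"HDL": 52.0, "TCH": 192.0, "TGY": 132.0}
_DEFAULT_LIPID_SDS = {"HDL": 13.0, "TCH": 35.0, "TGY": 75.0}


# ---------------------------------------------------------------------------
# Human cohort


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic human cohort.

    Lipid means/SDs are mg/dL (defaults are typical adult serum values).
    ``effect_r`` is the target population correlation magnitude for planted
    probes; ``nonlinear_fraction`` of them get the monotone cubic link.
    """

    n_subjects: int = 500
    n_probes: int = 1000
    n_true_probes: int = 20
    effect_r: float = 0.3
    nonlinear_fraction: float = 0.25
    lipid_means: dict = field(default_factory=lambda: dict(_DEFAULT_LIPID_MEANS))
    lipid_sds: dict = field(default_factory=lambda: dict(_DEFAULT_LIPID_SDS))
    sex_ratio: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_probes <= 0:
            raise ValueError("n_subjects and n_probes must be positive")
        if not 0 <= self.n_true_probes <= self.n_probes:
            raise ValueError("need 0 <= n_true_probes <= n_probes")
        if self.n_true_probes > 0 and not 0.0 < self.effect_r < 1.0:
            raise ValueError("effect_r must lie in (0, 1)")
        if not 0.0 <= self.nonlinear_fraction <= 1.0:
            raise ValueError("nonlinear_fraction must lie in [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for d in (self.lipid_means, self.lipid_sds):
            for k in LIPIDS:
                v = float(d[k])
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"non-finite or non-positive lipid parameter for {k}")


@lru_cache(maxsize=64)
def _calibrate_signal_weight(effect_r: float, link: str) -> float:
    """Solve for the signal weight w giving the target population correlation.

    Bisection against a fixed 200k-draw calibration sample (its own constant
    seed, independent of any cohort seed) — Monte-Carlo error ~0.002.
    Linear probes target Pearson r; cubic probes target Spearman rho, since
    the cubic link deliberately attenuates Pearson.
    """
    rng = np.random.default_rng(987_654_321)
    z = rng.standard_normal(200_000)
    eps = rng.standard_normal(200_000)
    if link == "cuberoot":
        u = np.sign(z) * np.abs(z) ** (1.0 / 3.0) / _CUBEROOT_SD
        z_ranks = rankdata(z)
        scale = _LATENT_SCALE_NONLINEAR
    else:
        u = z
        scale = _LATENT_SCALE

    def realized(w: float) -> float:
        beta = expit(scale * (w * u + np.sqrt(1.0 - w * w) * eps))
        if link == "cuberoot":
            rb = rankdata(beta)
            return float(np.corrcoef(rb, z_ranks)[0, 1])
        return float(np.corrcoef(beta, z)[0, 1])

    lo, hi = 0.0, 1.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if realized(mid) < effect_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _label_seed(seed: int, label: str) -> list[int]:
    return [seed & 0x7FFFFFFF, zlib.crc32(label.encode())]


def simulate_cohort(config: CohortConfig, cohort_label: str = "COHORT") -> CohortDataset:
    """Generate one phenotyped cohort with planted lipid-methylation signal.

    Probe-level ground truth (which probes are true, their lipid, sign and
    link) depends only on ``config.seed``, so two cohorts simulated from the
    same config under different labels share their true probes — the setting
    the two-cohort intersection stage assumes.  Subject-level randomness is
    keyed on (seed, label).  Deterministic: same config and label give
    byte-identical output.
    """
    config.validate()
    n, m = config.n_subjects, config.n_probes

    probe_ids = [f"cg{i:06d}" for i in range(m)]
    probe_rng = np.random.default_rng(np.random.SeedSequence(_label_seed(config.seed, "probes")))
    true_idx = np.sort(probe_rng.choice(m, size=config.n_true_probes, replace=False))
    signs = probe_rng.choice([-1.0, 1.0], size=config.n_true_probes)
    lipid_assign = [LIPIDS[i % len(LIPIDS)] for i in range(config.n_true_probes)]
    n_nonlin = int(round(config.nonlinear_fraction * config.n_true_probes))
    links = np.array(["linear"] * config.n_true_probes, dtype=object)
    if n_nonlin:
        pick = probe_rng.choice(config.n_true_probes, size=n_nonlin, replace=False)
        links[pick] = "cuberoot"

    rng = np.random.default_rng(np.random.SeedSequence(_label_seed(config.seed, cohort_label)))
    subj_ids = [f"{cohort_label}_{i:05d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    lipids = {
        k: rng.normal(float(config.lipid_means[k]), float(config.lipid_sds[k]), size=n)
        for k in LIPIDS
    }
    # serum lipids are positive; resample rare negatives from the folded tail
    for k in LIPIDS:
        lipids[k] = np.abs(lipids[k])

    betas = expit(_LATENT_SCALE * rng.standard_normal((m, n)))
    true_set = set(int(i) for i in true_idx)
    truth_rows = []
    for j, pi in enumerate(true_idx):
        lip = lipid_assign[j]
        z = (lipids[lip] - float(config.lipid_means[lip])) / float(config.lipid_sds[lip])
        if links[j] == "cuberoot":
            u = np.sign(z) * np.abs(z) ** (1.0 / 3.0) / _CUBEROOT_SD
            scale = _LATENT_SCALE_NONLINEAR
        else:
            u, scale = z, _LATENT_SCALE
        w = _calibrate_signal_weight(round(config.effect_r, 6), str(links[j]))
        eps = rng.standard_normal(n)
        betas[pi] = expit(scale * (signs[j] * w * u + np.sqrt(1.0 - w * w) * eps))
        truth_rows.append({
            "probe": probe_ids[pi], "lipid": lip, "sign": int(signs[j]),
            "link": str(links[j]), "target_r": config.effect_r,
        })
    assert len(true_set) == config.n_true_probes

    samples = pd.DataFrame(
        {"sex": sex, "cohort": cohort_label,
         "HDL": lipids["HDL"], "TCH": lipids["TCH"], "TGY": lipids["TGY"]},
        index=pd.Index(subj_ids, name="subject_id"),
    )
    beta_df = pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"), columns=subj_ids)
    truth = pd.DataFrame(truth_rows, columns=["probe", "lipid", "sign", "link", "target_r"])
    return CohortDataset(samples=samples, betas=beta_df, truth=truth)


# ---------------------------------------------------------------------------
# Species tree


@dataclass
class _TreeNode:
    height: float
    name: str | None = None
    children: tuple["_TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _quote_label(label: str) -> str:
    import re

    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class SpeciesTree:
    """Rooted binary ultrametric species tree with positive branch lengths."""

    root: _TreeNode
    leaves: tuple[str, ...]

    @property
    def newick(self) -> str:
        def render(node: _TreeNode, parent_h: float | None) -> str:
            if node.is_leaf:
                s = _quote_label(node.name or "")
            else:
                s = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
            if parent_h is not None:
                s += f":{parent_h - node.height:.10g}"
            return s

        return render(self.root, None) + ";"

    def node_heights(self) -> dict[str, float]:
        """Cophenetic (divergence-time) height of the MRCA for each leaf pair."""
        out: dict[tuple[str, str], float] = {}

        def walk(node: _TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            sub = [walk(c) for c in node.children]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a in sub[i]:
                        for b in sub[j]:
                            out[tuple(sorted((a, b)))] = node.height
            return [x for s in sub for x in s]

        walk(self.root)
        return out

    def cophenetic_distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.node_heights()[tuple(sorted((a, b)))]


def simulate_species_tree(n_species: int, seed: int,
                          labels: list[str] | None = None) -> SpeciesTree:
    """Random rooted binary tree by sequential random coalescence.

    Pairs of active lineages merge uniformly at random; waiting times are
    exponential with the coalescent rate k(k-1)/2.  Heights are rescaled so
    the root sits at 1.0, which makes Brownian-motion noise ratios
    interpretable downstream.  Deterministic given the seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if labels is None:
        labels = [f"Species_{i + 1:02d}" for i in range(n_species)]
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5EED]))
    active: list[_TreeNode] = [_TreeNode(height=0.0, name=lab) for lab in labels]
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        active.append(_TreeNode(height=t, children=(a, b)))
    root = active[0]

    scale = 1.0 / root.height

    def rescale(node: _TreeNode) -> _TreeNode:
        return _TreeNode(height=node.height * scale, name=node.name,
                         children=tuple(rescale(c) for c in node.children))

    return SpeciesTree(root=rescale(root), leaves=tuple(labels))


# ---------------------------------------------------------------------------
# Pan-mammalian dataset


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    max_lifespan: float  # years

    def validate(self) -> None:
        if not self.name:
            raise ValueError("empty species name")
        if not np.isfinite(self.max_lifespan) or self.max_lifespan <= 0:
            raise ValueError(f"max_lifespan must be positive for {self.name}")


@dataclass(frozen=True)
class TissueSpec:
    """One tissue: per-species sample count, additive offset, age slope.

    ``age_slope`` (beta units per age unit) is either a scalar applied to
    every probe or a mapping probe id -> slope for probe-specific aging.
    """

    name: str
    n_per_species: int = 25
    offset: float = 0.0
    age_slope: float | dict = 0.0

    def validate(self) -> None:
        if not self.name:
            raise ValueError("empty tissue name")
        if self.n_per_species < 1:
            raise ValueError(f"tissue {self.name}: need at least 1 sample per species")

    def slope_vector(self, probes: list[str]) -> np.ndarray:
        if isinstance(self.age_slope, dict):
            return np.array([float(self.age_slope.get(p, 0.0)) for p in probes])
        return np.full(len(probes), float(self.age_slope))


@dataclass(frozen=True)
class MammalConfig:
    species: tuple[SpeciesSpec, ...]
    tissues: tuple[TissueSpec, ...]
    brownian_sigma: float = 0.05   # per unit branch length, beta units
    noise_sd: float = 0.01         # residual SD, beta units
    shared_species_effect: bool = True
    lifespan_effect: float = 0.0   # beta units per unit centred log-lifespan
    lifespan_probe_fraction: float = 0.25
    sex_effect: float = 0.0        # added to females, subtracted from males
    seed: int = 0

    def validate(self) -> None:
        if not self.species or not self.tissues:
            raise ValueError("need at least one species and one tissue")
        for s in self.species:
            s.validate()
        for t in self.tissues:
            t.validate()
        if self.brownian_sigma < 0 or self.noise_sd < 0:
            raise ValueError("brownian_sigma and noise_sd must be non-negative")
        if not 0.0 <= self.lifespan_probe_fraction <= 1.0:
            raise ValueError("lifespan_probe_fraction must lie in [0, 1]")


def _brownian_on_tree(tree: SpeciesTree, root_values: np.ndarray, sigma: float,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One Brownian realisation per probe; returns leaf name -> value vector.

    Child value = parent value + N(0, sigma^2 * branch_length), branch
    length measured root-down (parent height - child height).
    """
    out: dict[str, np.ndarray] = {}

    def walk(node: _TreeNode, value: np.ndarray) -> None:
        if node.is_leaf:
            out[node.name] = value
            return
        for child in node.children:
            L = node.height - child.height
            step = rng.normal(0.0, sigma * np.sqrt(max(L, 0.0)), size=value.shape)
            walk(child, value + step)

    walk(tree.root, root_values)
    return out


def simulate_mammalian_dataset(tree: SpeciesTree, config: MammalConfig,
                               probes: list[str]) -> MammalDataset:
    """Generate the pan-mammalian dataset on a given species tree.

    Sample beta = species Brownian baseline (+ optional centred
    log-lifespan term on a random probe subset) + tissue offset +
    tissue age slope x age + sex effect + Gaussian noise, clipped to [0,1].
    Ages are uniform on (0, species max lifespan); sexes are balanced within
    each species x tissue block.  The planted baselines, slopes and offsets
    come back in ``MammalDataset.truth`` along with the clipped fraction.
    """
    config.validate()
    if not probes:
        raise ValueError("empty probe list")
    unknown = [s.name for s in config.species if s.name not in tree.leaves]
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")

    m = len(probes)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x3A]))
    root = rng.uniform(0.3, 0.7, size=m)

    n_life = int(round(config.lifespan_probe_fraction * m))
    life_idx = np.sort(rng.choice(m, size=n_life, replace=False)) if n_life else np.array([], dtype=int)
    lifespans = {s.name: s.max_lifespan for s in config.species}
    log_ls = {k: np.log(v) for k, v in lifespans.items()}
    mean_log = float(np.mean(list(log_ls.values())))

    # species-level Brownian baselines: one realisation shared by all tissues,
    # or an independent realisation per tissue
    if config.shared_species_effect:
        shared = _brownian_on_tree(tree, root, config.brownian_sigma, rng)
        baselines = {t.name: shared for t in config.tissues}
    else:
        baselines = {
            t.name: _brownian_on_tree(tree, root, config.brownian_sigma, rng)
            for t in config.tissues
        }

    cols: list[np.ndarray] = []
    ids: list[str] = []
    rows_sheet: list[dict] = []
    n_clipped = 0
    n_total = 0
    for sp in config.species:
        for ts in config.tissues:
            k = ts.n_per_species
            ages = rng.uniform(0.0, sp.max_lifespan, size=k)
            sexes = np.array(["F", "M"] * ((k + 1) // 2))[:k]
            slopes = ts.slope_vector(probes)
            base = baselines[ts.name][sp.name].copy()
            if n_life and config.lifespan_effect:
                base = base.copy()
                base[life_idx] += config.lifespan_effect * (log_ls[sp.name] - mean_log)
            block = (
                base[:, None]
                + ts.offset
                + slopes[:, None] * ages[None, :]
                + config.sex_effect * np.where(sexes == "F", 1.0, -1.0)[None, :]
                + rng.normal(0.0, config.noise_sd, size=(m, k))
            )
            n_clipped += int(np.sum((block < 0) | (block > 1)))
            n_total += block.size
            cols.append(np.clip(block, 0.0, 1.0))
            for i in range(k):
                sid = f"{sp.name}_{ts.name}_{i:03d}"
                ids.append(sid)
                rows_sheet.append({
                    "sample_id": sid, "species": sp.name, "tissue": ts.name,
                    "age": ages[i], "sex": sexes[i], "max_lifespan": sp.max_lifespan,
                })

    samples = pd.DataFrame(rows_sheet).set_index("sample_id")
    betas = pd.DataFrame(np.concatenate(cols, axis=1),
                         index=pd.Index(probes, name="probe_id"), columns=ids)
    truth = {
        "baselines": {
            tname: pd.DataFrame(vals, index=probes)
            for tname, vals in baselines.items()
        },
        "tissue_offsets": {t.name: t.offset for t in config.tissues},
        "age_slopes": {t.name: t.slope_vector(probes) for t in config.tissues},
        "lifespan_probes": [probes[i] for i in life_idx],
        "lifespan_effect": config.lifespan_effect,
        "clipped_fraction": n_clipped / max(n_total, 1),
        "tree_newick": tree.newick,
    }
    return MammalDataset(samples=samples, betas=betas, truth=truth)
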