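import numpy as np
import pandas as pd
import pytest

from lipisign import (CohortConfig, MammalConfig, SpeciesSpec, TissueSpec,
                      MammalDataset, simulate_cohort, simulate_mammalian_dataset,
                      simulate_species_tree)


@pytest.fixture(scope="session")
def signal_cohort():
    """Cohort with 5 strong linear planted probes (for recovery checks)."""
    cfg = CohortConfig(n_subjects=400, n_probes=120, n_true_probes=5,
                       effect_r=0.5, nonlinear_fraction=0.0, seed=11)
    return simulate_cohort(cfg, "ASAS")


@pytest.fixture(scope="session")
def small_mammal():
    """4 species x 2 tissues with shared species effects and planted slopes."""
    species = tuple(SpeciesSpec(n, ls) for n, ls in
                    [("Species_01", 80.0), ("Species_02", 25.0),
                     ("Species_03", 12.0), ("Species_04", 5.0)])
    tissues = (TissueSpec("Blood", 20, 0.0, -0.001),
               TissueSpec("Liver", 20, 0.04, -0.002))
    cfg = MammalConfig(species=species, tissues=tissues, brownian_sigma=0.08,
                       noise_sd=0.01, lifespan_effect=0.0, seed=7)
    tree = simulate_species_tree(4, seed=7, labels=[s.name for s in species])
    probes = [f"cg{i:06d}" for i in range(40)]
    return simulate_mammalian_dataset(tree, cfg, probes)


def make_toy_mammal(sheet_rows):
    """MammalDataset from a list of (species, tissue) pairs, one probe."""
    rows = []
    for i, (sp, ti) in enumerate(sheet_rows):
        rows.append({"sample_id": f"s{i:04d}", "species": sp, "tissue": ti,
                     "age": 1.0 + i % 7, "sex": "F" if i % 2 else "M",
                     "max_lifespan": 20.0})
    sheet = pd.DataFrame(rows).set_index("sample_id")
    rng = np.random.default_rng(0)
    betas = pd.DataFrame(rng.uniform(0.2, 0.8, size=(1, len(rows))),
                         index=pd.Index(["cg000000"], name="probe_id"),
                         columns=sheet.index)
    return MammalDataset(samples=sheet, betas=betas)
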