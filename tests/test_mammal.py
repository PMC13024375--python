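"""Probe projection, sample filters, age/lifespan correlations, identity score."""

import numpy as np
import pandas as pd
import pytest

from lipisign import (MammalConfig, MammalDataset, SpeciesSpec, TissueSpec,
                      age_correlation, filter_samples, lifespan_association,
                      project_probes, simulate_mammalian_dataset,
                      simulate_species_tree, tissue_identity_score)
from conftest import make_toy_mammal


class TestProjectProbes:
    def test_identity_and_set_arithmetic(self):
        p = project_probes(["cg1", "cg2", "cg3"], ["cg2", "cg3", "cg4"])
        assert p.probes == ("cg2", "cg3")
        assert p.n_retained == 2 and p.n_lost == 1
        same = project_probes(["cg1"], ["cg1"])
        assert same.probes == ("cg1",)

    def test_disjoint_and_empty_raise(self):
        with pytest.raises(ValueError):
            project_probes(["cg1"], ["cg2"])
        with pytest.raises(ValueError):
            project_probes([], ["cg2"])


def _toy_sheet():
    """Species A: 250 samples (t1=60, t2=40, five thin tissues of 30);
    species B: 150 samples in one abundant tissue."""
    rows = [("A", "t1")] * 60 + [("A", "t2")] * 40
    for k in range(5):
        rows += [("A", f"thin{k}")] * 30
    rows += [("B", "tB")] * 150
    return rows


class TestFilterSamples:
    def test_toy_sequential_semantics(self):
        ds = make_toy_mammal(_toy_sheet())
        out, rep = filter_samples(ds, min_species_n=200, min_tissue_n=50)
        assert rep.n_input == 400
        assert rep.n_after_species == 250  # only species A survives
        assert out.samples.shape[0] == 60  # then only tissue t1
        assert set(out.samples["species"]) == {"A"}
        assert set(out.samples["tissue"]) == {"t1"}

    def test_matches_bruteforce_filter(self):
        ds = make_toy_mammal(_toy_sheet())
        out, _ = filter_samples(ds, min_species_n=200, min_tissue_n=50)
        sheet = ds.samples
        sp_ok = sheet["species"].map(sheet["species"].value_counts()) >= 200
        surv = sheet[sp_ok]
        ti_ok = surv["tissue"].map(surv["tissue"].value_counts()) >= 50
        assert list(out.samples.index) == list(surv[ti_ok].index)

    def test_zero_thresholds_identity(self):
        ds = make_toy_mammal(_toy_sheet())
        out, _ = filter_samples(ds, min_species_n=0, min_tissue_n=0)
        assert out.samples.equals(ds.samples)

    def test_idempotent_when_groups_stay_abundant(self):
        rows = [("A", "t1")] * 120 + [("A", "t2")] * 100 + [("B", "t1")] * 30
        ds = make_toy_mammal(rows)
        once, _ = filter_samples(ds, min_species_n=100, min_tissue_n=50)
        twice, _ = filter_samples(once, min_species_n=100, min_tissue_n=50)
        assert list(once.samples.index) == list(twice.samples.index)

    def test_empty_result_raises(self):
        ds = make_toy_mammal([("A", "t1")] * 10)
        with pytest.raises(ValueError, match="filter"):
            filter_samples(ds, min_species_n=100, min_tissue_n=0)


def _flat_dataset(slope, n=200, noise=0.01, seed=0, lifespan=40.0):
    species = (SpeciesSpec("Species_01", lifespan),)
    tissues = (TissueSpec("T", n, 0.0, slope),)
    cfg = MammalConfig(species=species, tissues=tissues, brownian_sigma=0.0,
                       noise_sd=noise, seed=seed)
    tree = simulate_species_tree(2, seed=1, labels=["Species_01", "Species_02"])
    return simulate_mammalian_dataset(tree, cfg, [f"cg{i}" for i in range(3)])


class TestAgeCorrelation:
    def test_null_slope_gives_small_r(self):
        ds = _flat_dataset(0.0)
        tab = age_correlation(ds, "cg0", stratify_by="species")
        r = tab.iloc[0]["r"]
        assert abs(r) < 2 / np.sqrt(tab.iloc[0]["n"])

    @pytest.mark.parametrize("seed", range(5))
    def test_negative_slope_gives_strong_negative_r(self, seed):
        ds = _flat_dataset(-0.002, noise=0.01, seed=seed)
        tab = age_correlation(ds, "cg0", stratify_by="species")
        assert tab.iloc[0]["r"] < -0.5

    def test_small_stratum_flagged(self):
        ds = _flat_dataset(0.0, n=5)
        tab = age_correlation(ds, "cg0", stratify_by="species", min_n=10)
        assert tab.iloc[0]["flag"] == "low_n"
        assert np.isnan(tab.iloc[0]["r"])

    def test_invariant_to_affine_age_rescaling(self):
        ds = _flat_dataset(-0.002, seed=3)
        t_years = age_correlation(ds, "cg0", stratify_by="species")
        ds_months = MammalDataset(
            samples=ds.samples.assign(age=ds.samples["age"] * 12.0),
            betas=ds.betas)
        t_months = age_correlation(ds_months, "cg0", stratify_by="species")
        assert t_years.iloc[0]["r"] == pytest.approx(t_months.iloc[0]["r"], abs=1e-12)

    def test_unknown_stratification_raises(self):
        ds = _flat_dataset(0.0)
        with pytest.raises(ValueError):
            age_correlation(ds, "cg0", stratify_by="banana")


def _lifespan_dataset(gamma, seed=0):
    species = tuple(SpeciesSpec(f"Species_{i + 1:02d}", ls)
                    for i, ls in enumerate([2.0, 5.0, 12.0, 30.0, 60.0, 90.0]))
    tissues = (TissueSpec("Blood", 25),)
    cfg = MammalConfig(species=species, tissues=tissues, brownian_sigma=0.005,
                       noise_sd=0.005, lifespan_effect=gamma,
                       lifespan_probe_fraction=1.0, seed=seed)
    tree = simulate_species_tree(6, seed=seed, labels=[s.name for s in species])
    return simulate_mammalian_dataset(tree, cfg, [f"cg{i}" for i in range(4)])


class TestLifespanAssociation:
    def test_planted_lifespan_effect_recovered(self):
        ds = _lifespan_dataset(gamma=0.08, seed=5)
        r, p, n = lifespan_association(ds, "cg0", log_lifespan=True)
        assert n == 6
        assert r > 0.8

    def test_null_gamma_gives_weak_r(self):
        rs = [abs(lifespan_association(_lifespan_dataset(0.0, seed=s), "cg0")[0])
              for s in range(5)]
        assert np.median(rs) < 0.8  # no systematic lifespan signal

    def test_too_few_species(self):
        ds = make_toy_mammal([("A", "t")] * 5 + [("B", "t")] * 5 + [("C", "t")] * 5)
        with pytest.raises(ValueError, match="species"):
            lifespan_association(ds, "cg000000")

    def test_invariant_to_sample_counts(self):
        """One point per species: duplicating a species' samples changes nothing."""
        ds = _lifespan_dataset(gamma=0.08, seed=5)
        dup_ids = list(ds.samples.index) + list(ds.samples.index[:25])
        samples = ds.samples.loc[dup_ids].copy()
        samples.index = [f"s{i}" for i in range(len(dup_ids))]
        betas = ds.betas.loc[:, dup_ids].copy()
        betas.columns = samples.index
        ds2 = MammalDataset(samples=samples, betas=betas)
        r1, _, _ = lifespan_association(ds, "cg0")
        r2, _, _ = lifespan_association(ds2, "cg0")
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestTissueIdentity:
    def _two_tissue_ds(self, sep, seed=0):
        species = (SpeciesSpec("Species_01", 20.0),)
        tissues = (TissueSpec("Blood", 20, 0.0, 0.0),
                   TissueSpec("Liver", 20, sep, 0.0))
        cfg = MammalConfig(species=species, tissues=tissues, brownian_sigma=0.0,
                           noise_sd=0.01, seed=seed)
        tree = simulate_species_tree(2, seed=1, labels=["Species_01", "Species_02"])
        return simulate_mammalian_dataset(tree, cfg, [f"cg{i}" for i in range(10)])

    def test_separated_tissues_score_near_one(self):
        ds = self._two_tissue_ds(sep=0.3)
        assert tissue_identity_score(ds, ds.probes, label="tissue") > 0.9

    def test_shuffled_labels_score_near_zero(self):
        ds = self._two_tissue_ds(sep=0.3)
        rng = np.random.default_rng(1)
        shuffled = ds.samples.copy()
        shuffled["tissue"] = rng.permutation(shuffled["tissue"].to_numpy())
        ds2 = MammalDataset(samples=shuffled, betas=ds.betas)
        assert abs(tissue_identity_score(ds2, ds2.probes, label="tissue")) < 0.25

    def test_single_label_raises(self):
        ds = make_toy_mammal([("A", "t1")] * 10)
        with pytest.raises(ValueError):
            tissue_identity_score(ds, ["cg000000"], label="tissue")

    def test_offsets_vs_brownian_dominance(self):
        """Big tissue offsets -> tissue score beats species score; big
        Brownian species spread with tiny offsets -> the reverse."""
        species = tuple(SpeciesSpec(f"Species_{i + 1:02d}", 20.0) for i in range(3))
        tree = simulate_species_tree(3, seed=2, labels=[s.name for s in species])
        probes = [f"cg{i}" for i in range(12)]

        def build(offset, sigma):
            tissues = (TissueSpec("Blood", 10, 0.0, 0.0),
                       TissueSpec("Liver", 10, offset, 0.0))
            cfg = MammalConfig(species=species, tissues=tissues,
                               brownian_sigma=sigma, noise_sd=0.01, seed=3)
            return simulate_mammalian_dataset(tree, cfg, probes)

        tissue_dom = build(offset=0.3, sigma=0.005)
        assert (tissue_identity_score(tissue_dom, probes, "tissue")
                > tissue_identity_score(tissue_dom, probes, "species"))
        species_dom = build(offset=0.005, sigma=0.3)
        assert (tissue_identity_score(species_dom, probes, "species")
                > tissue_identity_score(species_dom, probes, "tissue"))


class TestHypiAgeConcordance:
    def test_exact_line_and_null(self):
        from lipisign import hypi_age_concordance

        probes = [f"cg{i:03d}" for i in range(10)]
        hypi = pd.DataFrame({
            "probe": probes, "lipid": "HDL", "sex": "F",
            "hypi": np.linspace(-2, 2, 10), "accepted": True,
        })
        corrs = pd.DataFrame({
            "stratum": "Species_01", "probe": probes,
            "r": np.linspace(-2, 2, 10), "p": 0.01, "n": 50, "flag": "",
        })
        fit = hypi_age_concordance(hypi, corrs)["F"]
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["r"] == pytest.approx(1.0)

        rng = np.random.default_rng(4)
        corrs_null = corrs.assign(r=rng.normal(size=10))
        fit0 = hypi_age_concordance(hypi, corrs_null)["F"]
        assert abs(fit0["r"]) < 0.8  # no systematic relation

    def test_too_few_shared_probes(self):
        from lipisign import hypi_age_concordance

        hypi = pd.DataFrame({"probe": ["cg1"], "lipid": "HDL", "sex": "F",
                             "hypi": [1.0], "accepted": [True]})
        corrs = pd.DataFrame({"stratum": ["s"], "probe": ["cg1"], "r": [0.5],
                              "p": [0.1], "n": [30], "flag": [""]})
        with pytest.raises(ValueError):
            hypi_age_concordance(hypi, corrs)

    @pytest.mark.parametrize("seed", range(5))
    def test_coupled_simulation_recovers_concordance(self, seed):
        """Mammalian age slopes planted proportional to human lipid effect
        signs produce a strong positive HyPi-vs-age-correlation relation."""
        from lipisign import (CohortConfig, hypi_age_concordance, score_cohort,
                              simulate_cohort)

        ccfg = CohortConfig(n_subjects=400, n_probes=60, n_true_probes=12,
                            effect_r=0.4, nonlinear_fraction=0.0, seed=seed)
        cohort = simulate_cohort(ccfg, "A")
        table = score_cohort(cohort, sex_strata=("all",))

        slope_map = {row["probe"]: 0.004 * row["sign"]
                     for _, row in cohort.truth.iterrows()}
        species = tuple(SpeciesSpec(f"Species_{i + 1:02d}", 30.0) for i in range(3))
        tissues = (TissueSpec("Blood", 60, 0.0, slope_map),)
        mcfg = MammalConfig(species=species, tissues=tissues, brownian_sigma=0.01,
                            noise_sd=0.01, seed=seed)
        tree = simulate_species_tree(3, seed=seed, labels=[s.name for s in species])
        mam = simulate_mammalian_dataset(tree, mcfg, list(cohort.probes))

        corrs = age_correlation(mam, list(cohort.probes), stratify_by="species")
        fit = hypi_age_concordance(table, corrs)["all"]
        assert fit["r"] > 0.7
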