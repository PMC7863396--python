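"""Synthetic cohort generator: structure, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dietmetab as dm
from dietmetab.errors import ConfigurationError, InputError


class TestConfigValidation:
    def test_default_cohort_sizes(self):
        cohort = dm.simulate_cohort(dm.default_config(seed=0, n_ions=80))
        assert cohort.n == 40
        counts = cohort.participants["diet"].value_counts()
        assert counts["OMN"] == 24 and counts["VGTR"] == 10 and counts["VGN"] == 6

    @pytest.mark.parametrize(
        "field,value,message",
        [
            ("group_sizes", (0, 1, 1), "group_sizes"),
            ("age_range", (5.0, 2.0), "age_range"),
            ("block_correlation", 1.0, "block_correlation"),
            ("sex_balance", 1.5, "sex_balance"),
            ("n_ions", 0, "n_ions"),
        ],
    )
    def test_invalid_fields_named_in_error(self, field, value, message):
        from dataclasses import replace

        cfg = replace(dm.default_config(seed=0, n_ions=80), **{field: value})
        with pytest.raises(ConfigurationError, match=message):
            cfg.validate()

    def test_effect_on_unknown_pathway_rejected(self):
        from dataclasses import replace

        cfg = dm.default_config(seed=0, n_ions=80)
        cfg = replace(cfg, effect_table={"nope": (1.0, 0.5)})
        with pytest.raises(ConfigurationError, match="nope"):
            cfg.validate()

    def test_negative_sd_rejected(self):
        spec = dm.BiomarkerSpec(
            "x", {g: 1.0 for g in ("OMN", "VGTR", "VGN")},
            {"OMN": -1.0, "VGTR": 1.0, "VGN": 1.0},
        )
        with pytest.raises(ConfigurationError, match="negative SD"):
            spec.validate("bad")


class TestDeterminism:
    def test_identical_seeds_identical_fixture_bytes(self, tmp_path):
        from dataclasses import replace

        cfg = dm.default_config(seed=42, n_ions=60,
                                group_sizes=(1, 1, 1))
        paths = {}
        for run in ("a", "b"):
            cohort = dm.simulate_biomarkers(dm.simulate_cohort(cfg), cfg)
            matrix = dm.simulate_metabolome(cohort, cfg)
            paths[run] = dm.write_fixture(cohort, matrix, tmp_path / run)
        for key in paths["a"]:
            assert paths["a"][key].read_bytes() == paths["b"][key].read_bytes()

    def test_substreams_independent(self):
        """Removing the biomarker spec must not perturb cohort draws."""
        from dataclasses import replace

        cfg = dm.default_config(seed=3, n_ions=60)
        stripped = replace(cfg, biomarker_spec={
            "only": dm.BiomarkerSpec("u", {g: 1.0 for g in ("OMN", "VGTR", "VGN")},
                                     {g: 0.1 for g in ("OMN", "VGTR", "VGN")})
        })
        c1 = dm.simulate_cohort(cfg)
        c2 = dm.simulate_cohort(stripped)
        pd.testing.assert_frame_equal(c1.participants, c2.participants)
        m1 = dm.simulate_metabolome(c1, cfg)
        m2 = dm.simulate_metabolome(c2, stripped)
        pd.testing.assert_frame_equal(m1.intensities, m2.intensities)


class TestCohortStructure:
    def test_ages_respect_configured_range(self):
        from dataclasses import replace

        cfg = dm.default_config(seed=5, n_ions=60)
        big = replace(cfg, group_sizes=(5000, 2500, 2500))
        ages = dm.simulate_cohort(big).participants["age_years"]
        assert ages.min() >= 1.42 and ages.max() <= 7.07

    def test_sex_balance(self):
        from dataclasses import replace

        cfg = replace(dm.default_config(seed=6, n_ions=60),
                      group_sizes=(4000, 500, 500))
        sexes = dm.simulate_cohort(cfg).participants["sex"]
        assert abs((sexes == "F").mean() - 0.5) < 0.03

    def test_unique_ids(self, cohort):
        assert cohort.participants["id"].is_unique


class TestMetabolome:
    def test_null_effects_give_uniform_welch_p(self):
        from dataclasses import replace

        cfg = dm.default_config(seed=8, n_ions=300)
        null = replace(cfg, effect_table={})
        cohort = dm.simulate_cohort(null)
        matrix = dm.simulate_metabolome(cohort, null)
        log = np.log10(matrix.intensities)
        a = log[cohort.ids_in_group("VGN")].to_numpy()
        b = log[cohort.ids_in_group("OMN")].to_numpy()
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_planted_fold_changes_recovered(self):
        """Vegan shift +1 log2 with attenuation 0.5 must come back as group
        log2 fold changes of about 1.0 (VGN) and 0.5 (VGTR) at large n."""
        errors_vgn, errors_vgtr = [], []
        for seed in (1, 2, 3):
            cfg = dm.SimConfig(
                group_sizes=(200, 200, 200),
                n_ions=30,
                pathway_spec={"P": [f"ion_{i + 1:04d}" for i in range(10)]},
                effect_table={"P": (1.0, 0.5)},
                block_correlation=0.0,
                biomarker_spec={},
                seed=seed,
            )
            cohort = dm.simulate_cohort(cfg)
            matrix = dm.simulate_metabolome(cohort, cfg)
            log2 = np.log2(matrix.intensities)
            members = cfg.pathway_spec["P"]
            omn = log2.loc[members, cohort.ids_in_group("OMN")].mean(axis=1)
            vgn = log2.loc[members, cohort.ids_in_group("VGN")].mean(axis=1)
            vgtr = log2.loc[members, cohort.ids_in_group("VGTR")].mean(axis=1)
            errors_vgn.append((vgn - omn).mean())
            errors_vgtr.append((vgtr - omn).mean())
        assert np.allclose(errors_vgn, 1.0, atol=0.1)
        assert np.allclose(errors_vgtr, 0.5, atol=0.1)

    def test_block_correlation_recovered(self):
        cfg = dm.SimConfig(
            group_sizes=(5000, 1, 1),
            n_ions=24,
            pathway_spec={"P": [f"ion_{i + 1:04d}" for i in range(20)]},
            effect_table={},
            block_correlation=0.3,
            biomarker_spec={},
            seed=9,
        )
        cohort = dm.simulate_cohort(cfg)
        matrix = dm.simulate_metabolome(cohort, cfg)
        log = np.log10(matrix.intensities.iloc[:20]).to_numpy()
        r = np.corrcoef(log)
        mean_r = r[np.triu_indices(20, k=1)].mean()
        assert mean_r == pytest.approx(0.30, abs=0.02)

    def test_intensities_strictly_positive(self, matrix):
        assert (matrix.intensities.to_numpy() > 0).all()


class TestBiomarkers:
    def test_mean_far_above_limit_censors_nearly_all(self):
        groups = ("OMN", "VGTR", "VGN")
        cfg = dm.SimConfig(
            n_ions=10,
            biomarker_spec={
                "b12_tc": dm.BiomarkerSpec(
                    "pmol/l", {g: 500.0 for g in groups},
                    {g: 20.0 for g in groups}, censor_limit=128.0,
                )
            },
            seed=2,
        )
        cohort = dm.simulate_biomarkers(dm.simulate_cohort(cfg), cfg)
        b12 = cohort.biomarker_values("b12_tc")
        assert b12["censored"].all()
        assert (b12["value"] == 128.0).all()

    def test_infinite_limit_never_censors(self, cohort):
        rbp = cohort.biomarker_values("rbp")
        assert not rbp["censored"].any()

    def test_vegan_vitamin_d_coverage(self):
        """Vegan total 25(OH)D mean 60, SD 3.5: about 95% of draws must fall
        inside 53-67 nmol/l."""
        from dataclasses import replace

        cfg = replace(dm.default_config(seed=4, n_ions=10),
                      group_sizes=(1, 1, 3000))
        cohort = dm.simulate_biomarkers(dm.simulate_cohort(cfg), cfg)
        vitd = cohort.biomarker_values("vitd_25oh")
        vegans = set(cohort.ids_in_group("VGN"))
        vals = vitd.loc[[i for i in vitd.index if i in vegans], "value"]
        inside = ((vals >= 53) & (vals <= 67)).mean()
        assert inside == pytest.approx(0.95, abs=0.02)

    def test_empty_biomarker_spec_rejected(self, cohort):
        from dataclasses import replace

        cfg = replace(dm.default_config(seed=0, n_ions=10), biomarker_spec={})
        with pytest.raises(ConfigurationError):
            dm.simulate_biomarkers(cohort, cfg)


class TestFixtureIO:
    def test_round_trip_preserves_data(self, cohort, matrix, tmp_path):
        paths = dm.write_fixture(cohort, matrix, tmp_path)
        loaded = dm.read_cohort(paths["cohort"], paths["biomarkers"])
        pd.testing.assert_frame_equal(loaded.participants, cohort.participants)
        pd.testing.assert_frame_equal(
            loaded.biomarkers.reset_index(drop=True),
            cohort.biomarkers.reset_index(drop=True),
        )
        from dietmetab.metabolomics import read_matrix

        m2 = read_matrix(paths["matrix"], paths["ions"])
        pd.testing.assert_frame_equal(m2.intensities, matrix.intensities)

    def test_write_read_write_identical(self, cohort, matrix, tmp_path):
        p1 = dm.write_fixture(cohort, matrix, tmp_path / "one")
        loaded = dm.read_cohort(p1["cohort"], p1["biomarkers"])
        from dietmetab.metabolomics import read_matrix

        m = read_matrix(p1["matrix"], p1["ions"])
        p2 = dm.write_fixture(loaded, m, tmp_path / "two")
        for key in ("cohort", "biomarkers", "matrix"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_biomarkers_valid_file(self, cohort, tmp_path):
        empty = dm.Cohort(cohort.participants.copy(),
                          cohort.biomarkers.iloc[0:0])
        paths = dm.write_fixture(empty, None, tmp_path)
        loaded = dm.read_cohort(paths["cohort"], paths["biomarkers"])
        assert loaded.biomarkers.empty
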