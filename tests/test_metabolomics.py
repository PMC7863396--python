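"""Accurate-mass annotation, fold changes, and zero handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietmetab as dm
from dietmetab import metabolomics as mb
from dietmetab.errors import DataError, FormatError, InputError


def tiny_matrix(mzs, intensities, participants=None):
    ids = [f"ion_{i + 1:04d}" for i in range(len(mzs))]
    participants = participants or [f"P{j}" for j in range(len(intensities[0]))]
    inten = pd.DataFrame(
        np.asarray(intensities, dtype=float),
        index=pd.Index(ids, name="ion_id"),
        columns=participants,
    )
    return mb.MetaboliteMatrix(pd.DataFrame({"ion_id": ids, "mz": mzs}), inten)


class TestFormulaMass:
    def test_water(self):
        assert dm.neutral_mass("H2O") == pytest.approx(18.0106, abs=5e-4)

    def test_glucose_deprotonated(self):
        assert dm.mz_from_formula("C6H12O6") == pytest.approx(179.0561, abs=5e-4)

    def test_empty_formula_rejected(self):
        with pytest.raises(FormatError):
            dm.neutral_mass("")

    def test_unknown_element_rejected(self):
        with pytest.raises(FormatError):
            dm.neutral_mass("C2Xx4")

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.sampled_from(["C", "H", "N", "O", "P", "S"]), min_size=1, max_size=4
        ),
        st.lists(
            st.sampled_from(["C", "H", "N", "O", "P", "S"]), min_size=1, max_size=4
        ),
    )
    def test_mass_additive_under_concatenation(self, a, b):
        fa, fb = "".join(a), "".join(b)
        assert dm.neutral_mass(fa + fb) == pytest.approx(
            dm.neutral_mass(fa) + dm.neutral_mass(fb), abs=1e-9
        )


class TestAnnotation:
    def test_isomers_both_retained(self):
        glucose_mz = dm.mz_from_formula("C6H12O6")
        matrix = tiny_matrix([glucose_mz], [[1.0, 2.0]])
        compounds = [
            dm.CompoundRecord("glucose", dm.neutral_mass("C6H12O6"), "C6H12O6"),
            dm.CompoundRecord("fructose", dm.neutral_mass("C6H12O6"), "C6H12O6"),
        ]
        ann = dm.annotate_peaks(matrix, compounds, tol=0.001)
        assert sorted(c for c, _ in ann["ion_0001"]) == ["fructose", "glucose"]

    def test_just_outside_tolerance_excluded(self):
        matrix = tiny_matrix([100.0], [[1.0, 2.0]])
        compounds = [
            dm.CompoundRecord("in", 100.0 + mb.PROTON_MASS + 0.001),
            dm.CompoundRecord("out", 100.0 + mb.PROTON_MASS + 0.001 + 1e-6),
        ]
        ann = dm.annotate_peaks(matrix, compounds, tol=0.001)
        assert [c for c, _ in ann["ion_0001"]] == ["in"]

    def test_matches_brute_force_oracle(self, rng):
        mzs = rng.uniform(80, 600, 60)
        matrix = tiny_matrix(mzs, rng.uniform(1, 10, size=(60, 3)))
        compounds = [
            dm.CompoundRecord(f"c{k}", m)
            for k, m in enumerate(rng.uniform(80, 601, 300))
        ]
        tol = 0.05
        ann = dm.annotate_peaks(matrix, compounds, tol=tol)
        for ion, mz in zip(matrix.ion_ids, mzs):
            expected = sorted(
                (
                    (c.compound_id, mz - (c.monoisotopic_mass - mb.PROTON_MASS))
                    for c in compounds
                    if abs(mz - (c.monoisotopic_mass - mb.PROTON_MASS)) <= tol
                ),
                key=lambda item: (abs(item[1]), item[0]),
            )
            got = ann.get(ion, [])
            assert [c for c, _ in got] == [c for c, _ in expected]

    def test_monotone_in_tolerance(self, rng):
        mzs = rng.uniform(80, 300, 30)
        matrix = tiny_matrix(mzs, rng.uniform(1, 10, size=(30, 3)))
        compounds = [
            dm.CompoundRecord(f"c{k}", m) for k, m in enumerate(rng.uniform(80, 301, 100))
        ]
        wide = dm.annotate_peaks(matrix, compounds, tol=0.1)
        narrow = dm.annotate_peaks(matrix, compounds, tol=0.01)
        for ion, cands in narrow.items():
            assert {c for c, _ in cands} <= {c for c, _ in wide[ion]}

    def test_compound_formula_mass_consistency_enforced(self):
        with pytest.raises(InputError):
            dm.CompoundRecord("bad", 100.0, "H2O")


class TestIsotopeSupport:
    def test_duplicated_vector_supported(self):
        base = [3.0, 5.0, 9.0, 2.0]
        matrix = tiny_matrix([200.0, 200.0 + mb.C13_SPACING], [base, base])
        assert dm.isotope_correlation_support(matrix, "ion_0001")

    def test_no_partner_unsupported(self):
        matrix = tiny_matrix([200.0, 260.0], [[1.0, 2, 3], [3.0, 2, 1]])
        assert not dm.isotope_correlation_support(matrix, "ion_0001")

    def test_uncorrelated_partner_mostly_unsupported(self, rng):
        hits = 0
        for _ in range(50):
            a, b = rng.normal(5, 1, 10), rng.normal(5, 1, 10)
            matrix = tiny_matrix([200.0, 200.0 + mb.C13_SPACING], [a, b])
            hits += dm.isotope_correlation_support(matrix, "ion_0001", r_min=0.7)
        assert hits <= 5


class TestHandleZeros:
    def test_identity_without_zeros(self):
        matrix = tiny_matrix([100.0], [[1.0, 2.0, 3.0]])
        out = dm.handle_zeros(matrix)
        pd.testing.assert_frame_equal(out.intensities, matrix.intensities)

    def test_half_min_rule(self):
        matrix = tiny_matrix([100.0], [[0.0, 4.0, 8.0]])
        out = dm.handle_zeros(matrix)
        np.testing.assert_allclose(out.intensities.iloc[0], [2.0, 4.0, 8.0])

    def test_all_zero_ion_named_in_error(self):
        matrix = tiny_matrix([100.0, 200.0], [[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(DataError, match="ion_0001"):
            dm.handle_zeros(matrix)

    def test_positive_and_order_preserving(self, rng):
        vals = rng.uniform(0, 10, size=(20, 8))
        vals[rng.random(vals.shape) < 0.2] = 0.0
        vals[:, 0] = rng.uniform(1, 10, 20)  # keep one positive per ion
        matrix = tiny_matrix(rng.uniform(80, 500, 20), vals)
        out = dm.handle_zeros(matrix).intensities.to_numpy()
        assert (out > 0).all()
        orig = matrix.intensities.to_numpy()
        pos = orig > 0
        assert np.array_equal(out[pos], orig[pos])


class TestFoldChanges:
    def test_reference_mean_maps_to_zero_and_doubling_to_one(self, cohort):
        omn = cohort.ids_in_group("OMN")
        others = [i for i in cohort.participants["id"] if i not in omn]
        vals = {pid: 10.0 for pid in omn}
        vals.update({others[0]: 20.0})
        vals.update({pid: 5.0 for pid in others[1:]})
        matrix = tiny_matrix(
            [100.0], [[vals[p] for p in cohort.participants["id"]]],
            participants=cohort.participants["id"].tolist(),
        )
        fc = dm.log2_fold_changes(matrix, cohort, reference="OMN")
        assert fc.loc["ion_0001", omn[0]] == pytest.approx(0.0)
        assert fc.loc["ion_0001", others[0]] == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self, cohort, matrix):
        fc = dm.log2_fold_changes(matrix, cohort)
        omn = cohort.ids_in_group("OMN")
        ion = matrix.ion_ids[7]
        pid = cohort.participants["id"].iloc[-1]
        expected = np.log2(
            matrix.intensities.loc[ion, pid]
            / matrix.intensities.loc[ion, omn].mean()
        )
        assert fc.loc[ion, pid] == pytest.approx(expected, abs=1e-12)

    def test_scaling_one_ion_shifts_its_fold_changes(self, cohort, matrix):
        scaled = mb.MetaboliteMatrix(
            matrix.ions.copy(), matrix.intensities.copy()
        )
        ion = matrix.ion_ids[0]
        scaled.intensities.loc[ion] *= 8.0
        fc0 = dm.log2_fold_changes(matrix, cohort)
        fc1 = dm.log2_fold_changes(scaled, cohort)
        # reference mean scales too, so per-individual FCs are unchanged
        np.testing.assert_allclose(fc1.loc[ion], fc0.loc[ion], atol=1e-10)

    def test_nonpositive_rejected(self, cohort):
        matrix = tiny_matrix(
            [100.0], [[0.0] * cohort.n],
            participants=cohort.participants["id"].tolist(),
        )
        with pytest.raises(DataError):
            dm.log2_fold_changes(matrix, cohort)


class TestPooledClasses:
    def test_pooled_group_sizes_mirror_membership(self, cohort, matrix):
        fc = dm.log2_fold_changes(dm.handle_zeros(matrix), cohort)
        classes = {"MCFA": matrix.ion_ids[:3], "LCFA": matrix.ion_ids[3:9]}
        box, tests = dm.pooled_class_comparison(fc, classes, cohort)
        mcfa = box[box["class"] == "MCFA"].set_index("diet")
        assert mcfa.loc["OMN", "n"] == 72  # 3 ions x 24 omnivores
        assert mcfa.loc["VGTR", "n"] == 30
        assert mcfa.loc["VGN", "n"] == 18
        lcfa = box[box["class"] == "LCFA"].set_index("diet")
        assert lcfa.loc["OMN", "n"] == 144
        assert set(tests["pair"]) == {"VGN-OMN", "VGTR-OMN"}

    def test_single_ion_class_reduces_to_ion_distribution(self, cohort, matrix):
        fc = dm.log2_fold_changes(dm.handle_zeros(matrix), cohort)
        ion = matrix.ion_ids[0]
        box, _ = dm.pooled_class_comparison(fc, {"solo": [ion]}, cohort)
        omn = cohort.ids_in_group("OMN")
        row = box[(box["class"] == "solo") & (box["diet"] == "OMN")].iloc[0]
        assert row["median"] == pytest.approx(np.median(fc.loc[ion, omn]))

    def test_box_statistics_match_sort_based_oracle(self, cohort, matrix, rng):
        fc = dm.log2_fold_changes(dm.handle_zeros(matrix), cohort)
        members = list(rng.choice(matrix.ion_ids, 4, replace=False))
        box, _ = dm.pooled_class_comparison(fc, {"cls": members}, cohort)
        for g in cohort.groups:
            pooled = np.sort(fc.loc[members, cohort.ids_in_group(g)].to_numpy().ravel())
            row = box[(box["class"] == "cls") & (box["diet"] == g)].iloc[0]
            assert row["min"] == pytest.approx(pooled[0])
            assert row["max"] == pytest.approx(pooled[-1])
            assert row["median"] == pytest.approx(np.median(pooled))

    def test_unknown_ion_rejected(self, cohort, matrix):
        fc = dm.log2_fold_changes(dm.handle_zeros(matrix), cohort)
        with pytest.raises(InputError):
            dm.pooled_class_comparison(fc, {"bad": ["nope"]}, cohort)
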