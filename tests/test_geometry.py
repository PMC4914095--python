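import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kturnlab import (
    GeometryParams,
    IncompleteInstanceError,
    SimulationParams,
    call_hbond,
    classify_bp_family,
    classify_conformation,
    distance,
    helix_width,
    simulate_structure,
    simulate_structures,
    width_statistics,
)
from kturnlab.geometry import _cis_or_trans

from conftest import apply_rigid_motion, random_rigid_motion

coords = st.floats(-100, 100, allow_nan=False, width=32)
point = st.tuples(coords, coords, coords).map(np.array)


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 0, 0), (0, 0, 0), 0.0),
            ((1, 0, 0), (0, 0, 0), 1.0),
            ((1, 2, 2), (0, 0, 0), 3.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert distance(a, b) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(a=point, b=point)
    def test_symmetric_and_zero_iff_equal(self, a, b):
        assert distance(a, b) == pytest.approx(distance(b, a))
        assert distance(a, a) == 0.0
        if not np.array_equal(a, b):
            assert distance(a, b) > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            distance((np.nan, 0, 0), (0, 0, 0))


class TestCallHbond:
    @pytest.mark.parametrize(
        "d,verdict", [(2.9, "bonded"), (4.3, "not_bonded"), (3.7, "ambiguous")]
    )
    def test_verdict_zones(self, d, verdict):
        call = call_hbond((0, 0, 0), (d, 0, 0))
        assert call.verdict == verdict
        assert call.distance == pytest.approx(d)

    def test_cutoffs_must_be_ordered(self):
        with pytest.raises(ValueError):
            GeometryParams(bonded_max=4.0, broken_min=3.5)


class TestClassifyConformation:
    def test_n3_core(self, n3_instance):
        call = classify_conformation(n3_instance)
        assert call.cls == "N3"
        assert call.d_O2p_N3 == pytest.approx(2.9, abs=1e-9)
        assert call.d_O2p_N1 == pytest.approx(5.2, abs=1e-9)
        assert call.d_N6_N3 == pytest.approx(2.9, abs=1e-9)

    def test_n1_core(self, n1_instance):
        call = classify_conformation(n1_instance)
        assert call.cls == "N1"
        assert call.d_O2p_N1 == pytest.approx(2.9, abs=1e-9)

    def test_extended_when_no_acceptor_bonded(self, n3_instance):
        n3_instance.residues["-1n"].atoms["O2'"] += np.array([0.0, 20.0, 0.0])
        assert classify_conformation(n3_instance).cls == "extended"

    def test_ambiguous_when_both_bonded_within_margin(self, n3_instance):
        # put the O2' donor nearly equidistant between the two ring nitrogens
        mid = 0.5 * (
            n3_instance.atom("2b", "N3") + n3_instance.atom("2b", "N1")
        ) + np.array([0.0, 2.5, 0.0])
        n3_instance.residues["-1n"].atoms["O2'"] = mid
        call = classify_conformation(n3_instance)
        assert call.cls == "ambiguous"

    def test_secondary_disagreement_downgrades(self, n3_instance):
        # break the A2b N6 - G2n N3 bond while leaving the primary N3 bond
        n3_instance.residues["2n"].atoms["N3"] += np.array([3.0, 0.0, 0.0])
        call = classify_conformation(n3_instance)
        assert call.cls == "ambiguous"
        assert any("secondary" in note for note in call.notes)

    def test_missing_atom_raises(self, n3_instance):
        del n3_instance.residues["2b"].atoms["N6"]
        with pytest.raises(IncompleteInstanceError):
            classify_conformation(n3_instance)

    def test_mutual_exclusivity_over_jittered_population(self):
        for cls in ("N3", "N1"):
            for inst in simulate_structures(cls, 25, 0.2, seed=9):
                call = classify_conformation(inst)
                assert call.cls in ("N3", "N1", "ambiguous", "extended")


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("cls", ["N3", "N1"])
    def test_all_observables_invariant(self, cls):
        rng = np.random.default_rng(17)
        inst, _ = simulate_structure(cls, SimulationParams(seed=3, jitter_sd=0.05))
        ref_call = classify_conformation(inst)
        ref_widths = {p: helix_width(inst, p).c1c1 for p in ("2b2n", "3b3n", "4b4n")}
        ref_family = classify_bp_family(inst)
        for _ in range(10):
            moved, _ = simulate_structure(cls, SimulationParams(seed=3, jitter_sd=0.05))
            rot, trans = random_rigid_motion(rng)
            apply_rigid_motion(moved, rot, trans)
            call = classify_conformation(moved)
            assert call.cls == ref_call.cls
            assert call.d_O2p_N3 == pytest.approx(ref_call.d_O2p_N3, abs=1e-9)
            assert call.d_O2p_N1 == pytest.approx(ref_call.d_O2p_N1, abs=1e-9)
            assert call.d_N6_N3 == pytest.approx(ref_call.d_N6_N3, abs=1e-9)
            for p, w in ref_widths.items():
                assert helix_width(moved, p).c1c1 == pytest.approx(w, abs=1e-9)
            fam = classify_bp_family(moved)
            assert (fam.orientation, fam.edge_b, fam.edge_n, fam.n_hbonds) == (
                ref_family.orientation,
                ref_family.edge_b,
                ref_family.edge_n,
                ref_family.n_hbonds,
            )


class TestHelixWidth:
    def test_template_widths(self, n3_instance, n1_instance):
        assert helix_width(n3_instance, "2b2n").c1c1 == pytest.approx(8.93, abs=1e-6)
        assert helix_width(n1_instance, "2b2n").c1c1 == pytest.approx(10.17, abs=1e-6)
        assert helix_width(n3_instance, "4b4n").c1c1 == pytest.approx(10.55, abs=1e-6)

    def test_coincident_c1_flagged_implausible(self, n3_instance):
        n3_instance.residues["4n"].atoms["C1'"] = n3_instance.atom("4b", "C1'").copy()
        rec = helix_width(n3_instance, "4b4n")
        assert rec.c1c1 == pytest.approx(0.0)
        assert rec.implausible

    def test_missing_c1_raises(self, n3_instance):
        del n3_instance.residues["4b"].atoms["C1'"]
        with pytest.raises(IncompleteInstanceError):
            helix_width(n3_instance, "4b4n")


class TestWidthStatistics:
    def test_hand_computed_mean_and_sample_sd(self):
        from kturnlab import WidthRecord

        records = [
            WidthRecord("a", "2b2n", 8.9, "N3"),
            WidthRecord("b", "2b2n", 9.0, "N3"),
            WidthRecord("c", "2b2n", 8.9, "N3"),
        ]
        stats = width_statistics(records)
        row = stats.iloc[0]
        assert row["mean"] == pytest.approx(8.9333333, abs=1e-6)
        # sample SD of {8.9, 9.0, 8.9}: sqrt(0.0066667 / 2)
        assert row["sd"] == pytest.approx(math.sqrt(0.006666667 / 2), abs=1e-6)
        assert row["n"] == 3
        assert stats.attrs["sd_estimator"] == "sample (ddof=1)"

    def test_single_record_sd_absent(self):
        from kturnlab import WidthRecord

        stats = width_statistics([WidthRecord("a", "3b3n", 9.6, "N3")])
        assert stats.iloc[0]["mean"] == pytest.approx(9.6)
        assert np.isnan(stats.iloc[0]["sd"])

    def test_collapse_averages_copies_first(self):
        from kturnlab import WidthRecord

        records = [
            WidthRecord("kt1/model1", "2b2n", 8.0, "N3"),
            WidthRecord("kt1/model2", "2b2n", 10.0, "N3"),
            WidthRecord("kt2/model1", "2b2n", 9.0, "N3"),
        ]
        stats = width_statistics(records, collapse=lambda iid: iid.split("/")[0])
        row = stats.iloc[0]
        assert row["n"] == 2
        assert row["mean"] == pytest.approx(9.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            width_statistics([])

    def test_class_means_on_synthetic_population(self):
        """Means over >=100 jittered copies per class stay inside the
        published class envelopes (8.93 +/- 0.22 vs 10.17 +/- 0.40 A)."""
        from kturnlab import WidthRecord

        records = []
        for cls in ("N3", "N1"):
            for inst in simulate_structures(cls, 100, 0.1, seed=21):
                records.append(helix_width(inst, "2b2n", cls))
        stats = width_statistics(records).set_index("cls")
        assert abs(stats.loc["N3", "mean"] - 8.93) < 0.22
        assert abs(stats.loc["N1", "mean"] - 10.17) < 0.40


class TestBasePairFamily:
    def test_canonical_gc_is_cis_wc(self):
        inst, _ = simulate_structure(
            "N3", SimulationParams(seed=2), pair_3b3n=("G", "C")
        )
        fam = classify_bp_family(inst)
        assert fam.n_hbonds == 3
        assert (fam.orientation, fam.edge_b, fam.edge_n) == ("cis", "WC", "WC")

    def test_ag_is_trans_hoogsteen_sugar(self):
        inst, _ = simulate_structure(
            "N3", SimulationParams(seed=2), pair_3b3n=("A", "G")
        )
        fam = classify_bp_family(inst)
        assert fam.orientation == "trans"
        assert fam.edge_b == "Hoogsteen"
        assert fam.edge_n == "sugar"
        assert fam.family == "trans-Hoogsteen/sugar"

    def test_separated_bases_undetermined(self, n3_instance):
        for atom in n3_instance.residues["3n"].atoms:
            n3_instance.residues["3n"].atoms[atom] += np.array([50.0, 0.0, 0.0])
        fam = classify_bp_family(n3_instance)
        assert fam.n_hbonds == 0
        assert fam.family == "undetermined"

    def test_cis_trans_matches_brute_force_on_random_points(self):
        """Projection-based side test agrees with an independent
        cross-product formulation on 1000 random coordinate sets."""

        def brute_force(n_b, c1_b, n_n, c1_n):
            axis = n_n - n_b
            s_b = np.cross(axis, c1_b - n_b)
            s_n = np.cross(axis, c1_n - n_n)
            d = float(np.dot(s_b, s_n))
            if np.linalg.norm(s_b) < 1e-9 or np.linalg.norm(s_n) < 1e-9:
                return None
            return "cis" if d > 0 else "trans"

        rng = np.random.default_rng(4)
        agree = 0
        for _ in range(1000):
            pts = rng.uniform(-10, 10, size=(4, 3))
            expected = brute_force(*pts)
            got = _cis_or_trans(*pts)
            assert got == expected
            agree += 1
        assert agree == 1000

    def test_distance_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            a, b = rng.uniform(-50, 50, size=(2, 3))
            expected = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            assert distance(a, b) == pytest.approx(expected, abs=1e-12)
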