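"""Descriptor pipeline: construction-oracle recovery, symmetries, ranking."""

import math

import numpy as np
import pytest

from conftest import apply_rigid_to_structure, random_rigid_transform

from ectodimer.descriptors import (
    DomainDefinition,
    ScissorDefinition,
    closure_angle,
    compare_to_reference,
    ensemble_distance_stats,
    ensemble_report,
    leg_hinge_angle,
    scissor_dihedral,
    tip_separation,
)
from ectodimer.structure_io import DimerMap, EnsembleStructure
from ectodimer.synthetic import ToyDimerSpec, build_toy_dimer, build_toy_ensemble


class TestConstructionRecovery:
    @pytest.mark.parametrize("scissor", [0.0, 10.0, 17.0, 25.0])
    def test_scissor_recovers_construction_value(self, scissor):
        st, truth = build_toy_dimer(ToyDimerSpec(scissor_angle=scissor))
        res = scissor_dihedral(st, 1, truth.dimer_map)
        assert res.value == pytest.approx(scissor, abs=1e-6)
        assert res.value == pytest.approx(abs(res.extras["signed"]), abs=1e-12)

    @pytest.mark.parametrize("tip", [0.0, 5.0, 12.0, 20.0])
    def test_tip_separation_recovers_construction_value(self, tip):
        st, truth = build_toy_dimer(ToyDimerSpec(tip_distance=tip))
        assert tip_separation(st, 1, truth.dimer_map).value == pytest.approx(tip, abs=1e-9)

    @pytest.mark.parametrize("closure", [60.0, 75.0, 80.0, 110.0])
    def test_closure_angle_recovers_construction_value(self, closure):
        st, truth = build_toy_dimer(ToyDimerSpec(closure_angle=closure))
        for chain in ("A", "B"):
            res = closure_angle(st, 1, chain, truth.dimer_map)
            assert res.value == pytest.approx(closure, abs=1e-6)

    @pytest.mark.parametrize("hinge", [0.0, 5.0, 20.0, 45.0])
    def test_hinge_angle_recovers_construction_value(self, hinge):
        st, truth = build_toy_dimer(ToyDimerSpec(hinge_angle_a=hinge))
        res = leg_hinge_angle(st, 1, truth.dimer_map, truth.reference_legs["A"], chain="A")
        assert res.value == pytest.approx(hinge, abs=1e-6)

    def test_noisy_recovery_within_three_sigma(self):
        # noise sigma propagates to the dihedral roughly as sigma/lever-arm;
        # assert agreement within 3x an empirical replicate spread
        sigma = 0.2
        values = []
        for seed in range(8):
            st, truth = build_toy_dimer(
                ToyDimerSpec(scissor_angle=17.0, noise_sd=sigma, seed=seed)
            )
            values.append(scissor_dihedral(st, 1, truth.dimer_map).value)
        values = np.array(values)
        spread = values.std(ddof=1)
        assert abs(values.mean() - 17.0) < 3 * max(spread, 1e-3)


class TestSymmetriesAndInvariance:
    def test_scissor_and_tip_symmetric_under_chain_swap(self):
        st, truth = build_toy_dimer(ToyDimerSpec(scissor_angle=13.0, tip_distance=9.0))
        fwd = truth.dimer_map
        rev = DimerMap(fwd.chain_b, fwd.chain_a)
        assert scissor_dihedral(st, 1, fwd).value == pytest.approx(
            scissor_dihedral(st, 1, rev).value, abs=1e-9
        )
        assert tip_separation(st, 1, fwd).value == pytest.approx(
            tip_separation(st, 1, rev).value, abs=1e-12
        )

    def test_mirror_symmetric_zero_scissor_dimer(self):
        st, truth = build_toy_dimer(ToyDimerSpec(scissor_angle=0.0))
        assert scissor_dihedral(st, 1, truth.dimer_map).value == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_descriptors_invariant_under_global_rigid_motion(self, seed):
        st, truth = build_toy_dimer(ToyDimerSpec(scissor_angle=17.0, hinge_angle_a=12.0))
        dm = truth.dimer_map
        rng = np.random.default_rng(seed)
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid_to_structure(st, rot, trans)
        assert scissor_dihedral(moved, 1, dm).value == pytest.approx(
            scissor_dihedral(st, 1, dm).value, abs=1e-6
        )
        assert tip_separation(moved, 1, dm).value == pytest.approx(
            tip_separation(st, 1, dm).value, abs=1e-6
        )
        assert closure_angle(moved, 1, "A", dm).value == pytest.approx(
            closure_angle(st, 1, "A", dm).value, abs=1e-6
        )
        # hinge: reference frame moves with the model (frame invariance is
        # built into the head-superposition step)
        ref = truth.reference_legs["A"]
        assert leg_hinge_angle(moved, 1, dm, ref, chain="A").value == pytest.approx(
            leg_hinge_angle(st, 1, dm, ref, chain="A").value, abs=1e-6
        )

    def test_missing_anchor_flagged_not_fabricated(self):
        st, truth = build_toy_dimer(ToyDimerSpec())
        tab = st.models[0]
        st_missing = EnsembleStructure([tab[tab["resnum"] != 249]])
        res = scissor_dihedral(st_missing, 1, truth.dimer_map)
        assert res.missing
        assert math.isnan(res.value)
        assert res.reason


class TestReferenceComparison:
    def test_self_comparison_is_zero(self, default_dimer):
        st, truth = default_dimer
        res = compare_to_reference(st, 1, st, (1, 501), truth.dimer_map)
        assert res.value == pytest.approx(0.0, abs=1e-9)
        assert res.extras["n_atoms"] == 2 * 501

    def test_congruent_sets_in_different_frames_are_zero(self, default_dimer):
        st, truth = default_dimer
        rng = np.random.default_rng(4)
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid_to_structure(st, rot, trans)
        res = compare_to_reference(moved, 1, st, (1, 501), truth.dimer_map)
        assert res.value == pytest.approx(0.0, abs=1e-8)

    def test_missing_residues_intersected_and_counted(self, default_dimer):
        st, truth = default_dimer
        tab = st.models[0]
        gappy = EnsembleStructure([tab[~((tab["chain"] == "A") & (tab["resnum"] <= 10))]])
        res = compare_to_reference(gappy, 1, st, (1, 501), truth.dimer_map)
        assert res.extras["n_atoms"] == 2 * 501 - 10

    def test_offset_reference_maps_align(self, default_dimer):
        st, truth = default_dimer
        shifted = EnsembleStructure([st.models[0].assign(resnum=st.models[0]["resnum"] + 24)])
        res = compare_to_reference(
            st, 1, shifted, (1, 501), truth.dimer_map,
            reference_map=DimerMap("A", "B", numbering_offset=24),
        )
        assert res.value == pytest.approx(0.0, abs=1e-9)

    def test_subunit_frame_differs_from_dimer_frame_for_hinged_model(self):
        st_a, truth = build_toy_dimer(ToyDimerSpec(hinge_angle_a=25.0))
        st_b, _ = build_toy_dimer(ToyDimerSpec(hinge_angle_a=0.0))
        dm = truth.dimer_map
        span = (1, 614)
        dimer = compare_to_reference(st_a, 1, st_b, span, dm, frame="dimer")
        sub = compare_to_reference(st_a, 1, st_b, span, dm, frame="subunit_b")
        assert dimer.value > 0
        assert sub.value != pytest.approx(dimer.value, abs=1e-6)


class TestEnsembleStats:
    def test_single_model_mean_equals_distance_sd_zero(self, default_dimer):
        st, truth = default_dimer
        stats = ensemble_distance_stats(
            st, truth.dimer_map, ("A", 614, "CA"), ("B", 614, "CA")
        )
        assert stats.n_models_used == 1
        assert stats.mean == pytest.approx(12.0, abs=1e-9)
        assert stats.sd == 0.0

    def test_twenty_model_arithmetic(self):
        specs = [ToyDimerSpec(tip_distance=float(d)) for d in range(1, 21)]
        ens, _ = build_toy_ensemble(specs)
        stats = ensemble_distance_stats(
            ens, DimerMap("A", "B"), ("A", 614, "CA"), ("B", 614, "CA")
        )
        assert stats.n_models_used == 20
        assert stats.mean == pytest.approx(10.5, abs=1e-9)
        assert stats.min == pytest.approx(1.0, abs=1e-9)
        assert stats.max == pytest.approx(20.0, abs=1e-9)
        assert stats.histogram_counts.sum() == 20

    def test_models_missing_atoms_excluded_and_reported(self):
        specs = [ToyDimerSpec(tip_distance=5.0), ToyDimerSpec(tip_distance=15.0)]
        ens, _ = build_toy_ensemble(specs)
        tab2 = ens.models[1]
        ens_gap = EnsembleStructure([ens.models[0], tab2[tab2["resnum"] != 614]])
        stats = ensemble_distance_stats(
            ens_gap, DimerMap("A", "B"), ("A", 614, "CA"), ("B", 614, "CA")
        )
        assert stats.excluded_models == (2,)
        assert stats.mean == pytest.approx(5.0, abs=1e-9)


class TestEnsembleReport:
    def test_ranking_matches_construction_order(self, graded_ensemble):
        ens, truth, specs = graded_ensemble
        report = ensemble_report(ens, DimerMap("A", "B"))
        table = report.table
        # construction order is juxtaposed (scissor 25) -> separated (10)
        assert list(table.sort_values("rank")["model"]) == list(range(1, 11))
        assert table.loc[table["model"] == 1, "label"].iloc[0] == "juxtaposed-like"
        assert table.loc[table["model"] == 10, "label"].iloc[0] == "separated-like"

    def test_scissor_and_tip_anticorrelated_series(self, graded_ensemble):
        ens, _, _ = graded_ensemble
        table = ensemble_report(ens, DimerMap("A", "B")).table
        by_scissor = table.sort_values("scissor_abs", ascending=False)["model"].tolist()
        by_tip = table.sort_values("tip_separation", ascending=True)["model"].tolist()
        assert by_scissor == by_tip
        assert np.all(np.diff(table.sort_values("model")["scissor_abs"]) < 0)
        assert np.all(np.diff(table.sort_values("model")["tip_separation"]) > 0)

    def test_identical_models_tie_with_stable_order(self):
        specs = [ToyDimerSpec() for _ in range(4)]
        ens, _ = build_toy_ensemble(specs)
        table = ensemble_report(ens, DimerMap("A", "B")).table
        assert set(table["rank"]) == {1}
        assert list(table["model"]) == [1, 2, 3, 4]
        assert set(table["label"]) == {""}

    def test_report_survives_missing_descriptor(self):
        st, truth = build_toy_dimer(ToyDimerSpec())
        tab = st.models[0]
        no_tip = EnsembleStructure([tab[tab["resnum"] != 614]])
        table = ensemble_report(no_tip, truth.dimer_map).table
        assert len(table) == 1
        assert math.isnan(table["tip_separation"].iloc[0])
        assert not math.isnan(table["scissor_abs"].iloc[0])
        assert "tip_separation" in table["missing"].iloc[0]

    def test_collinear_centroids_give_180_degrees(self):
        # synthetic degenerate head: all three domain centroids on one line
        from ectodimer.structure_io import ATOM_COLUMNS
        import pandas as pd

        rows = []
        rng = np.random.default_rng(0)
        for chain in ("A", "B"):
            shift = 0.0 if chain == "A" else 200.0
            for span, center in (((7, 200), 0.0), ((260, 285), 30.0), ((317, 470), 60.0)):
                residues = list(range(span[0], span[1] + 1))
                jit = rng.normal(scale=2.0, size=(len(residues), 3))
                jit -= jit.mean(axis=0)
                for r, j in zip(residues, jit):
                    rows.append((chain, r, "", "GLY", "CA", "C",
                                 center + j[0] + shift, j[1], j[2], False))
        st = EnsembleStructure([pd.DataFrame(rows, columns=ATOM_COLUMNS)])
        res = closure_angle(st, 1, "A", DimerMap("A", "B"))
        assert res.value == pytest.approx(180.0, abs=1e-6)

    def test_closure_coverage_threshold_flags_missing(self):
        st, truth = build_toy_dimer(ToyDimerSpec())
        tab = st.models[0]
        # drop > half of Domain I
        drop = (tab["chain"] == "A") & tab["resnum"].between(7, 110)
        res = closure_angle(EnsembleStructure([tab[~drop]]), 1, "A", truth.dimer_map)
        assert res.missing
        assert "coverage" in res.reason
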