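"""Triad measurement and locked/unlocked pocket classification."""

import dataclasses

import numpy as np
import pytest

from groovestate.pocket_state import (MeasurementError, PocketState,
                                      TriadMeasurement, classify_a_pocket,
                                      classify_f_pocket, measure_groove)
from groovestate.structure_io import StructureModel, resolve_chain_mapping
from groovestate.synthetic import (FixtureSpec, make_fixture_model,
                                   make_fixture_structure)
from conftest import rigid_motion

CFG = {"heavy_chains": ["A"]}


def _a_measurement(distance, flipped):
    return TriadMeasurement(pocket="A", his70_tyr99_distance=distance,
                            phe9_chi1=-60.0, phe9_regime="gauche_minus",
                            phe9_unlocked_conformation=flipped)


def _f_measurement(regime, arg97=False, his114=False, his74=False,
                   asp77=False):
    chi = {"trans": 180.0, "gauche_minus": -60.0, "gauche_plus": 60.0}[regime]
    return TriadMeasurement(pocket="F", tyr116_chi1=chi, tyr116_regime=regime,
                            arg97_tyr116_bonded=arg97,
                            his114_tyr116_bonded=his114,
                            tyr116_his74_bonded=his74,
                            tyr116_asp77_bonded=asp77)


class TestAPocketClassification:
    def test_bonded_and_reference_rotamer_is_locked(self):
        assert classify_a_pocket(_a_measurement(3.40, False)) == PocketState.LOCKED

    def test_released_and_flipped_is_unlocked(self):
        assert classify_a_pocket(_a_measurement(4.3, True)) == PocketState.UNLOCKED

    def test_mixed_evidence_is_indeterminate(self):
        assert classify_a_pocket(_a_measurement(3.4, True)) == \
            PocketState.INDETERMINATE
        assert classify_a_pocket(_a_measurement(4.0, False)) == \
            PocketState.INDETERMINATE

    def test_pure_function(self):
        m = _a_measurement(3.2, False)
        assert classify_a_pocket(m) == classify_a_pocket(
            dataclasses.replace(m))


class TestFPocketClassification:
    def test_gauche_minus_with_his114_bond_is_unlocked(self):
        m = _f_measurement("gauche_minus", arg97=True, his114=True)
        assert classify_f_pocket(m) == PocketState.UNLOCKED

    def test_trans_with_helix_partner_is_locked(self):
        assert classify_f_pocket(_f_measurement("trans", his74=True)) == \
            PocketState.LOCKED
        assert classify_f_pocket(_f_measurement("trans", asp77=True)) == \
            PocketState.LOCKED

    def test_arg97_only_is_partially_unlocked(self):
        m = _f_measurement("trans", arg97=True)
        assert classify_f_pocket(m) == PocketState.PARTIALLY_UNLOCKED

    def test_partial_beats_locked_when_both_fire(self):
        m = _f_measurement("trans", arg97=True, his74=True)
        assert classify_f_pocket(m) == PocketState.PARTIALLY_UNLOCKED

    def test_unlocked_beats_partial(self):
        m = _f_measurement("gauche_minus", arg97=True, his114=True, his74=True)
        assert classify_f_pocket(m) == PocketState.UNLOCKED

    def test_no_pattern_is_indeterminate(self):
        assert classify_f_pocket(_f_measurement("gauche_plus")) == \
            PocketState.INDETERMINATE


class TestMeasureGroove:
    def test_two_molecule_distances(self):
        """Two asymmetric-unit molecules with distinct His70-Tyr99 spacings."""
        model = make_fixture_model([
            FixtureSpec.for_states("locked", "unlocked",
                                   his70_tyr99_distance=3.40),
            FixtureSpec.for_states("unlocked", "unlocked",
                                   his70_tyr99_distance=3.52, phe9_chi1=180.0),
        ])
        mappings = resolve_chain_mapping(model,
                                         {"heavy_chains": ["A", "B"]})
        report = measure_groove(model, mappings=mappings)
        d1 = report.measurements["1"]["A"].his70_tyr99_distance
        d2 = report.measurements["2"]["A"].his70_tyr99_distance
        assert round(d1, 2) == 3.40
        assert round(d2, 2) == 3.52
        assert report.states["1"]["A"] == PocketState.LOCKED
        assert report.states["2"]["A"] == PocketState.UNLOCKED

    def test_generator_roundtrip_within_tolerance(self):
        spec = FixtureSpec.for_states("unlocked", "partially_unlocked",
                                      his70_tyr99_distance=4.1,
                                      phe9_chi1=175.0, seed=5)
        model = make_fixture_structure(spec)
        report = measure_groove(model, config=CFG)
        a = report.measurements["1"]["A"]
        f = report.measurements["1"]["F"]
        assert a.his70_tyr99_distance == pytest.approx(4.1, abs=1e-3)
        assert a.phe9_chi1 == pytest.approx(175.0, abs=1e-3)
        assert f.tyr116_chi1 == pytest.approx(spec.tyr116_chi1, abs=1e-3)
        assert f.distances["arg97_tyr116"] == pytest.approx(
            spec.bonded_distance, abs=1e-3)

    def test_missing_groove_residue_is_named(self):
        model = make_fixture_structure(FixtureSpec())
        atoms = [a for a in model.atoms if a.residue_number != 114]
        broken = StructureModel(entry_id="BROKEN", atoms=atoms)
        with pytest.raises(MeasurementError, match="his114"):
            measure_groove(broken, config=CFG)

    def test_rigid_motion_preserves_states(self, rng):
        spec = FixtureSpec.for_states("unlocked", "unlocked", seed=2)
        model = make_fixture_structure(spec)
        ref = measure_groove(model, config=CFG).states["1"]
        for _ in range(5):
            q, t = rigid_motion(rng)
            moved = StructureModel(
                entry_id=model.entry_id,
                atoms=[dataclasses.replace(
                    a, position=tuple(q @ np.asarray(a.position) + t))
                    for a in model.atoms])
            states = measure_groove(moved, config=CFG).states["1"]
            assert states == ref


class TestStateRoundTrip:
    @pytest.mark.parametrize("a_state", ["locked", "unlocked"])
    @pytest.mark.parametrize("f_state", ["locked", "unlocked",
                                         "partially_unlocked"])
    def test_classification_recovers_generator_intent(self, a_state, f_state):
        for seed in range(3):
            spec = FixtureSpec.for_states(a_state, f_state, seed=seed,
                                          noise_sigma=0.05)
            model = make_fixture_structure(spec)
            states = measure_groove(model, config=CFG).states["1"]
            assert states["A"].value == a_state
            assert states["F"].value == f_state
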