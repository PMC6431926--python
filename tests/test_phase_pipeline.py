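"""Transition detection, ensemble labelling, crossover location, and the
phase-diagram assembly, on synthetic curves and tiny simulations."""

import json

import numpy as np
import pandas as pd
import pytest

from helibundle.phase_pipeline import (CrossoverResult, PhaseDiagram,
                                       assemble_phase_diagram,
                                       detect_transitions, dominant_label,
                                       ensemble_labels, ground_state_crossover,
                                       transitions_from_records)
from helibundle.structure_analysis import (AMORPHOUS_SOLID, COMPACT, LIQUID,
                                           RANDOM_COIL, SINGLE_HELIX,
                                           TWO_HELIX_BUNDLE)


@pytest.fixture
def temps():
    return np.linspace(0.1, 2.0, 40)


class TestDetectTransitions:
    def test_single_gaussian_bump(self, temps):
        y = 1.0 + 3.0 * np.exp(-((temps - 0.9) / 0.15) ** 2)
        sigs = detect_transitions(temps, y)
        peaks = [s for s in sigs if s.kind == "peak"]
        assert len(peaks) == 1
        assert abs(peaks[0].T_location - 0.9) <= temps[1] - temps[0]
        assert not [s for s in sigs if s.kind == "shoulder"]

    def test_monotone_curve_has_no_signatures(self, temps):
        assert detect_transitions(temps, np.sqrt(temps)) == []
        assert detect_transitions(temps, 2.0 - temps) == []

    def test_two_bumps_in_order(self, temps):
        y = (np.exp(-((temps - 0.5) / 0.1) ** 2)
             + 2 * np.exp(-((temps - 1.5) / 0.1) ** 2))
        peaks = [s for s in detect_transitions(temps, y) if s.kind == "peak"]
        assert [round(p.T_location, 1) for p in peaks] == [0.5, 1.5]

    def test_shoulder_on_rising_curve(self, temps):
        # convex rise with an embedded logistic step -> bounded concave island
        y = 0.8 * (temps - 0.1) ** 2 + 2.0 / (1 + np.exp(-(temps - 0.8) / 0.08))
        sigs = detect_transitions(temps, y)
        shoulders = [s for s in sigs if s.kind == "shoulder"]
        assert len(shoulders) == 1
        assert 0.7 < shoulders[0].T_location < 1.2
        assert not [s for s in sigs if s.kind == "peak"]

    def test_error_bars_suppress_noise_peaks(self, temps):
        rng = np.random.default_rng(0)
        y = 1.0 + 0.01 * rng.normal(size=len(temps))
        err = np.full(len(temps), 0.1)
        assert all(s.kind != "peak"
                   for s in detect_transitions(temps, y, err))

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            detect_transitions([0.1, 0.2], [1.0, 2.0])


class TestDominantLabel:
    def test_modal(self):
        label, tie = dominant_label([SINGLE_HELIX] * 60 + [TWO_HELIX_BUNDLE] * 40)
        assert label == SINGLE_HELIX and not tie

    def test_tie_breaks_toward_more_ordered(self):
        label, tie = dominant_label([SINGLE_HELIX] * 50 + [RANDOM_COIL] * 50)
        assert label == SINGLE_HELIX and tie

    def test_compact_refined_by_freezing_position(self):
        assert dominant_label([COMPACT] * 10, T=0.1, freezing_T=0.5) == \
            (AMORPHOUS_SOLID, False)
        assert dominant_label([COMPACT] * 10, T=0.9, freezing_T=0.5) == \
            (LIQUID, False)

    def test_empty_ensemble(self):
        with pytest.raises(ValueError):
            dominant_label([])


class TestCrossover:
    def test_bracketed_midpoint(self):
        res = ground_state_crossover([8, 10, 12, 14], ["A", "A", "B", "B"],
                                     "A", "B")
        assert res == CrossoverResult(True, 11.0, 1.0, (10.0, 12.0))

    def test_unsorted_input(self):
        res = ground_state_crossover([14, 8, 12, 10], ["B", "A", "B", "A"],
                                     "A", "B")
        assert res.s_tau == 11.0

    def test_gap_with_intermediate_label(self):
        res = ground_state_crossover([8, 10, 12, 14], ["A", "A", "C", "B"],
                                     "A", "B")
        assert res.bracketed
        assert res.s_tau == 12.0 and res.uncertainty == 2.0

    def test_monotone_not_bracketed(self):
        res = ground_state_crossover([8, 10, 12], ["A", "A", "A"], "A", "B")
        assert not res.bracketed
        res = ground_state_crossover([8, 10, 12], ["B", "B", "A"], "A", "B")
        assert not res.bracketed


def _synthetic_records(labels_by_T, e_scale=1.0, n_frames=120, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for T, label in labels_by_T:
        rows.append(pd.DataFrame({
            "T": T,
            "E": rng.normal(scale=e_scale * T, size=n_frames),
            "q1": -1.0, "q2": -0.5, "label": label}))
    return pd.concat(rows, ignore_index=True)


class TestPhaseDiagram:
    def test_uniform_labels_no_boundaries(self):
        temps = [0.1, 0.3, 0.9, 1.5, 2.2]
        results = {s: _synthetic_records([(T, RANDOM_COIL) for T in temps],
                                         seed=i)
                   for i, s in enumerate([2.0, 6.0])}
        pd_ = assemble_phase_diagram(results)
        assert set(pd_.table.label) == {RANDOM_COIL}
        assert pd_.boundaries == []

    def test_two_region_boundary(self):
        temps = [0.1, 0.3, 0.9, 1.5, 2.2]
        def labels(stau):
            return [(T, SINGLE_HELIX if (stau > 4 and T < 1.0) else RANDOM_COIL)
                    for T in temps]
        results = {s: _synthetic_records(labels(s), seed=int(s))
                   for s in [2.0, 6.0]}
        pd_ = assemble_phase_diagram(results)
        axes = {b["axis"] for b in pd_.boundaries}
        assert "T" in axes and "s_tau" in axes
        t_bounds = [b for b in pd_.boundaries if b["axis"] == "T"]
        assert any(abs(b["T"] - 1.2) < 0.31 for b in t_bounds)

    def test_min_frames_enforced(self):
        results = {1.0: _synthetic_records([(0.5, RANDOM_COIL)], n_frames=5)}
        with pytest.raises(ValueError):
            assemble_phase_diagram(results)

    def test_serialization(self, tmp_path):
        temps = [0.1, 0.5, 1.0]
        results = {3.0: _synthetic_records([(T, RANDOM_COIL) for T in temps])}
        diagram = assemble_phase_diagram(results)
        diagram.to_csv(tmp_path / "phases.csv")
        diagram.to_json(tmp_path / "phases.json")
        back = pd.read_csv(tmp_path / "phases.csv")
        assert list(back.columns) == ["s_tau", "T", "label", "n_frames",
                                      "tie_flag"]
        payload = json.loads((tmp_path / "phases.json").read_text())
        assert "signatures" in payload and "boundaries" in payload


class TestEnsembleLabels:
    def test_compact_split_by_freezing_peak(self):
        temps = [0.1, 0.5, 1.5]
        records = _synthetic_records(
            [(0.1, COMPACT), (0.5, COMPACT), (1.5, RANDOM_COIL)])
        from helibundle.phase_pipeline import TransitionSignature
        sigs = [TransitionSignature(0.3, "peak", "cv", 1.0)]
        out = ensemble_labels(records, sigs)
        assert out.set_index("T").label.to_dict() == {
            0.1: AMORPHOUS_SOLID, 0.5: LIQUID, 1.5: RANDOM_COIL}


class TestCli:
    def test_run_classify_phases_roundtrip(self, tmp_path):
        from click.testing import CliRunner
        from helibundle.cli import main

        runner = CliRunner()
        out = tmp_path / "sweepdir"
        res = runner.invoke(main, [
            "sweep", "--n", "10", "--stau", "0,5", "--replicas", "4",
            "--equil", "50", "--measure", "400", "--sample-interval", "2",
            "--seed", "3", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "scan.csv").exists()
        sub = sorted(out.glob("stau_*"))
        assert len(sub) == 2
        assert (sub[0] / "observables.csv").exists()
        assert (sub[0] / "ground_state.xyz").exists()

        res = runner.invoke(main, [
            "classify", str(sub[0] / "ground_state.xyz"),
            "--out", str(tmp_path / "labels.csv")])
        assert res.exit_code == 0, res.output
        labels = pd.read_csv(tmp_path / "labels.csv")
        assert "label" in labels.columns and len(labels) == 1

        res = runner.invoke(main, [
            "phases", str(out), "--out", str(tmp_path / "phases"),
            "--min-frames", "50"])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(tmp_path / "phases.csv")
        assert {"s_tau", "T", "label"} <= set(table.columns)

    def test_run_command_writes_tables(self, tmp_path):
        from click.testing import CliRunner
        from helibundle.cli import main

        runner = CliRunner()
        out = tmp_path / "run1"
        res = runner.invoke(main, [
            "run", "--n", "10", "--stau", "20", "--replicas", "3",
            "--equil", "50", "--measure", "300", "--sample-interval", "3",
            "--seed", "2", "--out", str(out)])
        assert res.exit_code == 0, res.output
        rec = pd.read_csv(out / "observables.csv")
        assert {"sweep", "T", "E", "q1", "q2"} <= set(rec.columns)
        assert (out / "acceptance.csv").exists()
        assert (out / "swap_stats.csv").exists()
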