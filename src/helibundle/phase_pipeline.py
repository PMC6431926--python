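"""Temperature–torsion-strength phase analysis.

For every torsion strength S_tau, transition temperatures are located
as extrema of fluctuation quantities: peaks of the heat capacity (and
of |d<q1>/dT|, |d<q2>/dT|) that exceed their jackknife error, plus
"shoulders" — interior concave islands of Cv(T) that do not contain a
peak and persist under 2x coarser temperature sampling.  Combining the
per-(S_tau, T) dominant structure labels with these signatures yields
the hyperphase diagram over the (S_tau, T) plane for a fixed chain
length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .model_core import ModelParams
from .observables import heat_capacity_curve, mean_curve
from .remc import RunConfig, run_remc
from .structure_analysis import (AMORPHOUS_SOLID, COMPACT, LIQUID,
                                 ORDERED_LABELS, ClassifierThresholds,
                                 classify)

__all__ = [
    "TransitionSignature", "detect_transitions", "transitions_from_records",
    "dominant_label", "ensemble_labels", "ground_state_scan",
    "CrossoverResult", "ground_state_crossover", "PhaseDiagram",
    "assemble_phase_diagram",
]


@dataclass(frozen=True)
class TransitionSignature:
    """A transition indicator at temperature T_location."""

    T_location: float
    kind: str        # "peak" | "shoulder"
    source: str      # "cv" | "dq1_dT" | "dq2_dT"
    strength: float


def detect_transitions(temperatures, values, errors=None,
                       source: str = "cv") -> list[TransitionSignature]:
    """Locate peaks and shoulders in a fluctuation curve.

    Peaks: interior local maxima whose prominence exceeds the local
    jackknife error (if provided).  Shoulders: bounded concave islands
    of the curve (sign pattern +,-,+ of the second finite difference)
    that contain no peak and persist when every other temperature point
    is dropped.
    """
    T = np.asarray(temperatures, float)
    y = np.asarray(values, float)
    if T.size < 3:
        raise ValueError("need at least 3 temperature points")
    err = np.zeros_like(y) if errors is None else np.nan_to_num(
        np.asarray(errors, float))
    sigs: list[TransitionSignature] = []
    idx, _ = find_peaks(y)
    if idx.size:
        prom = peak_prominences(y, idx)[0]
        keep = prom > err[idx]
        idx = idx[keep]
        for i, pr in zip(idx, prom[keep]):
            sigs.append(TransitionSignature(float(T[i]), "peak", source,
                                            float(pr)))
    peak_idx = set(int(i) for i in idx)
    d2 = np.gradient(np.gradient(y, T), T)
    # curvature significance floor: a real shoulder bends the curve by a
    # non-negligible fraction of its range over a few grid spacings
    dt = np.mean(np.diff(T))
    floor = 1e-6 * max(np.ptp(y), 1e-300) / dt**2
    concave = d2 < -floor
    # bounded concave islands
    j = 1
    while j < len(T) - 1:
        if concave[j] and not concave[j - 1]:
            j2 = j
            while j2 < len(T) and concave[j2]:
                j2 += 1
            if j2 < len(T):  # bounded on the right
                island = range(j, j2)
                if not any((i in peak_idx or i + 1 in peak_idx
                            or i - 1 in peak_idx) for i in island):
                    lo, hi = T[j - 1], T[min(j2, len(T) - 1)]
                    if _persists_when_coarse(T, y, lo, hi):
                        k = min(island, key=lambda i: d2[i])
                        sigs.append(TransitionSignature(
                            float(T[k]), "shoulder", source, float(-d2[k])))
            j = j2
        else:
            j += 1
    return sorted(sigs, key=lambda s: s.T_location)


def _persists_when_coarse(T, y, lo, hi) -> bool:
    """A concave point remains inside [lo, hi] at 2x coarser sampling."""
    for offset in (0, 1):
        Tc, yc = T[offset::2], y[offset::2]
        if Tc.size < 3:
            continue
        d2c = np.gradient(np.gradient(yc, Tc), Tc)
        inside = (Tc >= lo) & (Tc <= hi)
        if np.any(d2c[inside] < 0):
            return True
    return False


def transitions_from_records(records: pd.DataFrame,
                             n_bins: int = 20) -> list[TransitionSignature]:
    """Signatures from Cv(T) plus the temperature derivatives of <q1>, <q2>."""
    cvdf = heat_capacity_curve(records, n_bins)
    sigs = detect_transitions(cvdf["T"], cvdf["cv"], cvdf["cv_err"], "cv")
    for col, src in (("q1", "dq1_dT"), ("q2", "dq2_dT")):
        if col not in records.columns:
            continue
        mdf = mean_curve(records, col)
        dq = np.abs(np.gradient(mdf[col].to_numpy(), mdf["T"].to_numpy()))
        for s in detect_transitions(mdf["T"], dq, None, src):
            if s.kind == "peak":
                sigs.append(s)
    return sorted(sigs, key=lambda s: s.T_location)


def dominant_label(labels, T: float | None = None,
                   freezing_T: float | None = None) -> tuple[str, bool]:
    """Modal frame label of an ensemble; ties break toward the more
    ordered label (and are flagged).  Frame-level ``compact`` is
    refined to liquid / amorphous_solid by position relative to the
    freezing signature when available."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty ensemble")
    counts = pd.Series(labels).value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index,
                     key=lambda l: ORDERED_LABELS.index(l))
    label, tie = winners[0], len(winners) > 1
    if label == COMPACT and T is not None and freezing_T is not None:
        label = AMORPHOUS_SOLID if T < freezing_T else LIQUID
    return label, tie


def ensemble_labels(records: pd.DataFrame,
                    signatures: list[TransitionSignature] | None = None,
                    min_frames: int = 100) -> pd.DataFrame:
    """Dominant label per temperature slot of one (N, S_tau) run."""
    freezing_T = None
    if signatures:
        peaks = [s for s in signatures if s.kind == "peak" and s.source == "cv"]
        if peaks:
            freezing_T = min(p.T_location for p in peaks)
    rows = []
    for T, grp in records.groupby("T", sort=True):
        if len(grp) < min_frames:
            raise ValueError(
                f"only {len(grp)} frames at T={T}; need >= {min_frames}")
        label, tie = dominant_label(grp["label"], T, freezing_T)
        rows.append({"T": T, "label": label, "n_frames": len(grp),
                     "tie_flag": tie})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground-state scans and crossovers
# ---------------------------------------------------------------------------

def ground_state_scan(stau_values, base_config: RunConfig,
                      params: ModelParams | None = None,
                      thresholds: ClassifierThresholds | None = None,
                      results_out: dict | None = None,
                      quench_candidates: bool = True) -> pd.DataFrame:
    """Run REMC at each S_tau and identify the putative ground state.

    With ``quench_candidates`` (the default protocol), the lowest-energy
    sampled frame of *each* observed structure type is quenched by local
    minimisation and the overall quenched minimum is reported.  This is
    the standard anneal-and-quench treatment of putative ground states:
    raw sampled minima are biased toward whichever basin the coldest
    replica happens to occupy, whereas competing structure types visited
    at intermediate temperatures are resolved by their T -> 0 energies.
    """
    from .structure_analysis import quench

    rows = []
    for i, stau in enumerate(stau_values):
        cfg = replace(base_config, s_tau=float(stau),
                      seed=base_config.seed + 7919 * i)
        res = run_remc(cfg, params)
        if results_out is not None:
            results_out[float(stau)] = res
        candidates = [res.ground_state]
        if quench_candidates:
            candidates += list(res.label_minima.values())
        best_e, best_pos = math.inf, None
        for reg in candidates:
            if reg.conformation is None:
                continue
            if quench_candidates:
                pos, e = quench(reg.conformation, res.params)
            else:
                pos, e = reg.conformation, reg.e_min
            if e < best_e:
                best_e, best_pos = e, pos
        lab = classify(best_pos, res.params, thresholds)
        rows.append({"s_tau": float(stau), "e_min": best_e,
                     "label": lab.label, **{k: v for k, v in
                                            lab.diagnostics.items()
                                            if k in ("n_segments", "q1", "q2")}})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossoverResult:
    bracketed: bool
    s_tau: float | None = None
    uncertainty: float | None = None
    interval: tuple | None = None


def ground_state_crossover(stau_values, labels, from_label: str,
                           to_label: str) -> CrossoverResult:
    """Locate the S_tau where the putative ground-state label switches.

    Reported as the midpoint of the bracketing interval between the
    last ``from_label`` grid point and the first subsequent
    ``to_label`` point, with half the interval width as uncertainty.
    """
    stau = [float(s) for s in stau_values]
    labels = list(labels)
    order = np.argsort(stau)
    stau = [stau[i] for i in order]
    labels = [labels[i] for i in order]
    first_to = None
    for i, lab in enumerate(labels):
        if lab == to_label and any(l == from_label for l in labels[:i]):
            first_to = i
            break
    if first_to is None:
        return CrossoverResult(False)
    last_from = max(i for i in range(first_to) if labels[i] == from_label)
    lo, hi = stau[last_from], stau[first_to]
    return CrossoverResult(True, 0.5 * (lo + hi), 0.5 * (hi - lo), (lo, hi))


# ---------------------------------------------------------------------------
# hyperphase diagram
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Dominant-structure grid over (S_tau, T) with transition annotations."""

    table: pd.DataFrame                      # s_tau, T, label, n_frames, tie_flag
    signatures: pd.DataFrame                 # s_tau, T, kind, source, strength
    boundaries: list = field(default_factory=list)  # label-change polyline points

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "signatures": self.signatures.to_dict(orient="records"),
            "boundaries": self.boundaries,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def assemble_phase_diagram(results: dict[float, pd.DataFrame],
                           min_frames: int = 100) -> PhaseDiagram:
    """Build the hyperphase diagram from per-S_tau observable records.

    ``results`` maps S_tau to a records table (columns T, E, q1, q2,
    label).  Missing grid cells raise rather than being interpolated.
    """
    if not results:
        raise ValueError("no sweep results")
    tables = []
    sig_rows = []
    for stau in sorted(results):
        records = results[stau]
        sigs = transitions_from_records(records)
        df = ensemble_labels(records, sigs, min_frames)
        df.insert(0, "s_tau", stau)
        tables.append(df)
        for s in sigs:
            sig_rows.append({"s_tau": stau, "T": s.T_location, "kind": s.kind,
                             "source": s.source, "strength": s.strength})
    table = pd.concat(tables, ignore_index=True)
    signatures = pd.DataFrame(sig_rows,
                              columns=["s_tau", "T", "kind", "source",
                                       "strength"])
    boundaries = []
    # boundaries in T (within an S_tau column) at label changes
    for stau, grp in table.groupby("s_tau"):
        g = grp.sort_values("T").reset_index(drop=True)
        for i in range(len(g) - 1):
            if g.loc[i, "label"] != g.loc[i + 1, "label"]:
                boundaries.append({
                    "s_tau": float(stau),
                    "T": 0.5 * (g.loc[i, "T"] + g.loc[i + 1, "T"]),
                    "between": [g.loc[i, "label"], g.loc[i + 1, "label"]],
                    "axis": "T"})
    # boundaries in S_tau (within a T row) at label changes
    for T, grp in table.groupby("T"):
        g = grp.sort_values("s_tau").reset_index(drop=True)
        for i in range(len(g) - 1):
            if g.loc[i, "label"] != g.loc[i + 1, "label"]:
                boundaries.append({
                    "s_tau": 0.5 * (g.loc[i, "s_tau"] + g.loc[i + 1, "s_tau"]),
                    "T": float(T),
                    "between": [g.loc[i, "label"], g.loc[i + 1, "label"]],
                    "axis": "s_tau"})
    return PhaseDiagram(table, signatures, boundaries)
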