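"""Canonical estimators and order parameters.

* ``q1`` / ``q2`` — the non-bonded Lennard-Jones energy split by bond
  separation: pairs at most 6 bonds apart (but non-bonded, i.e. j >=
  i+2) contribute to q1, pairs more than 6 bonds apart to q2.  A single
  helical segment has essentially no contacts beyond 6 bonds, so
  ``q2frac = q2 / (q1 + q2)`` discriminates single helices (~0) from
  helix bundles (> 0).
* heat capacity from energy fluctuations, ``Cv = var(E) / T^2`` with
  ``k_B = 1``, with jackknife error bars over contiguous bins.
* lowest-energy (putative ground state) bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as _k
from .model_core import ModelParams

__all__ = [
    "Q_SEPARATION_CUT", "compute_q1_q2", "q2frac", "heat_capacity",
    "heat_capacity_jackknife", "heat_capacity_curve", "mean_curve",
    "q2frac_histogram", "q2frac_histograms", "GroundStateRegister",
    "track_ground_state",
]

Q_SEPARATION_CUT = 6  # bonds: q1 takes separations 2..6, q2 takes > 6
_Q2FRAC_TOL = 1e-12


def compute_q1_q2(pos: np.ndarray, p: ModelParams) -> tuple[float, float]:
    """Short- and long-range non-bonded LJ energies (include the S_LJ scale)."""
    pos = np.ascontiguousarray(pos, dtype=float)
    short, long_ = _k.lj_split(pos, p.sigma, p.rc, p.vc, Q_SEPARATION_CUT)
    return p.s_lj * float(short), p.s_lj * float(long_)


def q2frac(q1: float, q2: float) -> float:
    """q2 / (q1 + q2); NaN sentinel when the total contact energy vanishes
    (no-contact coils), to be excluded from histograms."""
    tot = q1 + q2
    if abs(tot) < _Q2FRAC_TOL:
        return math.nan
    return q2 / tot


def heat_capacity(energies: np.ndarray, temperature: float) -> float:
    """Cv = (<E^2> - <E>^2) / T^2 in units of k_B."""
    e = np.asarray(energies, float)
    if e.size < 2:
        raise ValueError("need at least 2 samples for a heat capacity")
    return float(np.var(e) / temperature**2)


def heat_capacity_jackknife(energies: np.ndarray, temperature: float,
                            n_bins: int = 20) -> tuple[float, float]:
    """Heat capacity with a delete-one-bin jackknife error estimate.

    Contiguous binning makes the estimate robust to autocorrelation on
    the scale of the bin length.
    """
    e = np.asarray(energies, float)
    cv = heat_capacity(e, temperature)
    n_bins = min(n_bins, e.size)
    if n_bins < 2:
        return cv, math.nan
    edges = np.linspace(0, e.size, n_bins + 1).astype(int)
    reps = []
    for b in range(n_bins):
        mask = np.ones(e.size, bool)
        mask[edges[b]:edges[b + 1]] = False
        reps.append(np.var(e[mask]) / temperature**2)
    reps = np.array(reps)
    err = math.sqrt((n_bins - 1) / n_bins * np.sum((reps - reps.mean())**2))
    return cv, err


def heat_capacity_curve(records: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Per-temperature Cv with jackknife errors from an observable table
    (columns: T, E)."""
    rows = []
    for T, grp in records.groupby("T", sort=True):
        cv, err = heat_capacity_jackknife(grp["E"].to_numpy(), T, n_bins)
        rows.append({"T": T, "cv": cv, "cv_err": err, "n": len(grp)})
    return pd.DataFrame(rows)


def mean_curve(records: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per-temperature mean of an observable column (e.g. q1, q2)."""
    out = records.groupby("T", sort=True)[column].mean().reset_index()
    out.columns = ["T", column]
    return out


def q2frac_histogram(q1: np.ndarray, q2: np.ndarray,
                     bins: int | np.ndarray = 25,
                     range_: tuple[float, float] = (0.0, 1.0)):
    """Normalised q2frac histogram; NaN sentinels (no-contact frames)
    are excluded.  Returns (bin_centers, density)."""
    q1 = np.asarray(q1, float)
    q2 = np.asarray(q2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = q1 + q2
        f = np.where(np.abs(tot) < _Q2FRAC_TOL, math.nan, q2 / tot)
    f = f[np.isfinite(f)]
    density, edges = np.histogram(f, bins=bins, range=range_, density=True)
    if f.size == 0:
        density = np.zeros_like(density)
    return 0.5 * (edges[:-1] + edges[1:]), density


def q2frac_histograms(records: pd.DataFrame, T: float,
                      bins: int = 25) -> pd.DataFrame:
    """Per-S_tau normalised q2frac histograms of the canonical ensemble
    at temperature T (records need columns s_tau, T, q1, q2)."""
    sel = records[np.isclose(records["T"], T)]
    rows = []
    for stau, grp in sel.groupby("s_tau", sort=True):
        centers, dens = q2frac_histogram(grp["q1"].to_numpy(),
                                         grp["q2"].to_numpy(), bins)
        if len(grp) == 0 or not np.any(dens):
            empty = True
        else:
            empty = False
        for c, d in zip(centers, dens):
            rows.append({"s_tau": stau, "T": T, "bin_center": c,
                         "density": d, "empty": empty})
    return pd.DataFrame(rows)


@dataclass
class GroundStateRegister:
    """Minimum-energy conformation seen so far (putative ground state)."""

    e_min: float = math.inf
    conformation: np.ndarray | None = None
    sweep: int | None = None
    temperature: float | None = None
    history: list = field(default_factory=list)  # (sweep, e_min) improvements

    def update(self, energy: float, pos: np.ndarray,
               sweep: int | None = None,
               temperature: float | None = None) -> bool:
        """Record a strictly lower-energy conformation; returns True on update."""
        if energy < self.e_min:
            self.e_min = float(energy)
            self.conformation = np.array(pos, dtype=float, copy=True)
            self.sweep = sweep
            self.temperature = temperature
            self.history.append((sweep, float(energy)))
            return True
        return False


def track_ground_state(stream) -> GroundStateRegister:
    """Fold a stream of (energy, conformation[, sweep[, temperature]])
    tuples into a GroundStateRegister."""
    reg = GroundStateRegister()
    for item in stream:
        reg.update(*item)
    return reg
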