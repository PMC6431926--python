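"""Single-temperature Metropolis sampler.

Two update types, mirroring the sampling protocol the model is studied
with:

* **displacement** — move one uniformly chosen monomer to a uniform
  position inside a cube of side ``rd`` centred on its current
  position.  Weighted to be proposed ``3 N`` times more often than the
  torsion update.
* **torsion pivot** — choose a bond uniformly, rotate all monomers on
  one (random) side rigidly about the bond axis by an angle uniform in
  ``[-pi, pi]``.  This changes exactly one dihedral and the cross
  Lennard-Jones contacts; bonds and bending angles are untouched.

Proposals are accepted with the Metropolis probability
``min(1, exp(-dE / T))`` (``k_B = 1``); proposals that violate the FENE
stretching limit are rejected outright.

The displacement range ``rd`` is calibrated before measurement by a
multiplicative controller targeting ~50% acceptance, then frozen.

A numba fast path (:func:`helibundle._kernels.mc_block`) consumes the
same RNG stream in the same order as :func:`metropolis_step`, so both
paths generate identical trajectories from identical seeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from .model_core import EnergyBreakdown, ModelParams, total_energy

__all__ = [
    "MoveSchedule", "MCState", "DisplacementMove", "TorsionMove",
    "propose_displacement", "propose_torsion", "metropolis_accept",
    "metropolis_step", "run_sweeps", "tune_rd",
]


@dataclass
class MoveSchedule:
    """Move mix and displacement-range calibration settings.

    ``displacement_weight_factor * n`` is the relative proposal weight
    of displacement vs. torsion updates (default factor 3, i.e. a
    torsion update once per ``3 n + 1`` proposals on average).
    """

    displacement_weight_factor: int = 3
    rd: float = 0.3
    rd_target_acceptance: float = 0.5
    rd_acceptance_band: tuple[float, float] = (0.45, 0.55)
    rd_tuning_window_sweeps: int = 50
    rd_tuning_max_iter: int = 100

    def p_displacement(self, n: int) -> float:
        w = self.displacement_weight_factor * n
        return w / (w + 1.0)


@dataclass
class MCState:
    """One Markov chain: conformation, cached energy, temperature, RNG."""

    positions: np.ndarray
    params: ModelParams
    temperature: float
    rng: np.random.Generator
    energy: float = 0.0
    n_proposed: dict = field(default_factory=lambda: {"disp": 0, "tor": 0})
    n_accepted: dict = field(default_factory=lambda: {"disp": 0, "tor": 0})

    @classmethod
    def from_conformation(cls, pos, params, temperature, rng) -> "MCState":
        pos = np.array(pos, dtype=float, order="C", copy=True)
        st = cls(pos, params, float(temperature), rng)
        st.energy = total_energy(pos, params).e_total
        return st

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def energy_breakdown(self) -> EnergyBreakdown:
        return total_energy(self.positions, self.params)

    def resync_energy(self, tol: float = 1e-6) -> float:
        """Recompute the energy from scratch; warn on accumulation drift."""
        exact = self.energy_breakdown().e_total
        if abs(exact - self.energy) > tol * max(1.0, abs(exact)):
            warnings.warn(f"incremental energy drift: {self.energy - exact:.3e}")
        self.energy = exact
        return exact

    def acceptance_rate(self, kind: str) -> float:
        p = self.n_proposed[kind]
        return self.n_accepted[kind] / p if p else math.nan


@dataclass(frozen=True)
class DisplacementMove:
    index: int
    new_position: np.ndarray


@dataclass(frozen=True)
class TorsionMove:
    bond: int
    rotate_suffix: bool
    angle: float


def propose_displacement(state: MCState, schedule: MoveSchedule) -> DisplacementMove:
    """Uniform monomer, uniform offset in the cube of side rd."""
    rng = state.rng
    i = int(rng.integers(0, state.n))
    off = np.array([rng.random() - 0.5, rng.random() - 0.5, rng.random() - 0.5])
    return DisplacementMove(i, state.positions[i] + schedule.rd * off)


def propose_torsion(state: MCState) -> TorsionMove:
    """Uniform bond, uniform side, uniform angle in [-pi, pi]."""
    rng = state.rng
    k = int(rng.integers(0, state.n - 1))
    suffix = rng.random() < 0.5
    phi = (2.0 * rng.random() - 1.0) * math.pi
    return TorsionMove(k, suffix, phi)


def metropolis_accept(de: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule, kB = 1.  Draws from ``rng`` only when 0 < dE < inf."""
    if de <= 0.0:
        return True
    if de == math.inf:
        return False
    return rng.random() < math.exp(-de / temperature)


def metropolis_step(state: MCState, schedule: MoveSchedule) -> bool:
    """One attempted update (reference path); returns True if accepted."""
    p = state.params
    rng = state.rng
    if rng.random() < schedule.p_displacement(state.n):
        move = propose_displacement(state, schedule)
        de = _k.displacement_delta(state.positions, move.index,
                                   move.new_position, *p._tuple())
        state.n_proposed["disp"] += 1
        if metropolis_accept(de, state.temperature, rng):
            state.positions[move.index] = move.new_position
            state.energy += de
            state.n_accepted["disp"] += 1
            return True
        return False
    move = propose_torsion(state)
    scratch = np.empty_like(state.positions)
    lo, hi = _k._rotate_side(state.positions, scratch, move.bond, move.angle,
                             move.rotate_suffix)
    de = _k._pivot_dE(state.positions, scratch, lo, hi, move.bond,
                      p.sigma, p.rc, p.vc, p.tau0, p.s_lj, p.s_tau)
    state.n_proposed["tor"] += 1
    if metropolis_accept(de, state.temperature, rng):
        state.positions[lo:hi] = scratch[lo:hi]
        state.energy += de
        state.n_accepted["tor"] += 1
        return True
    return False


def run_sweeps(state: MCState, schedule: MoveSchedule, n_sweeps: int) -> None:
    """Fast path: ``n_sweeps * n`` attempted updates via the numba kernel."""
    run_updates(state, schedule, n_sweeps * state.n)


def run_updates(state: MCState, schedule: MoveSchedule, n_updates: int) -> None:
    p = state.params
    e, ad, pd_, at, pt = _k.mc_block(
        state.positions, state.energy, n_updates, state.temperature,
        schedule.rd, schedule.p_displacement(state.n), state.rng, *p._tuple())
    state.energy = float(e)
    state.n_accepted["disp"] += int(ad)
    state.n_proposed["disp"] += int(pd_)
    state.n_accepted["tor"] += int(at)
    state.n_proposed["tor"] += int(pt)


def tune_rd(state: MCState, schedule: MoveSchedule) -> float:
    """Calibrate rd so displacement acceptance lands in the target band.

    Multiplicative controller ``rd <- rd * sqrt(acc / target)`` over
    measurement windows of ``rd_tuning_window_sweeps`` sweeps; frozen
    afterwards.  Warns and keeps the last value if the controller does
    not settle within ``rd_tuning_max_iter`` iterations.
    """
    lo, hi = schedule.rd_acceptance_band
    target = schedule.rd_target_acceptance
    for _ in range(schedule.rd_tuning_max_iter):
        before_p = state.n_proposed["disp"]
        before_a = state.n_accepted["disp"]
        run_sweeps(state, schedule, schedule.rd_tuning_window_sweeps)
        prop = state.n_proposed["disp"] - before_p
        acc = (state.n_accepted["disp"] - before_a) / max(prop, 1)
        if lo <= acc <= hi:
            return schedule.rd
        factor = math.sqrt(max(acc, 0.02) / target)
        schedule.rd = min(max(schedule.rd * factor, 1e-4), 10.0)
    warnings.warn(
        f"rd tuning did not converge; keeping rd={schedule.rd:.4g}")
    return schedule.rd
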