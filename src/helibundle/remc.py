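"""Replica-exchange (parallel tempering) Monte Carlo driver.

M replicas run Metropolis sampling at a fixed, geometrically spaced
temperature ladder (default 32 temperatures in [0.03, 2.5]).  Every
``swap_interval_updates`` attempted updates per replica a conformation
exchange is attempted between neighbouring temperature slots with
probability ``min(1, exp[(beta_a - beta_b)(E_a - E_b)])``; edges
alternate between the even pairs (0-1, 2-3, ...) and the odd pairs
(1-2, 3-4, ...).  Conformations travel; temperatures, displacement
ranges and RNG streams stay attached to their slot, so the M slots
always hold the M temperatures bijectively.

Runs are fully reproducible: one seeded, independent RNG stream per
slot plus a dedicated stream for swap decisions, all spawned from the
single config seed; execution is serial.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .mc_engine import MCState, MoveSchedule, run_updates, tune_rd
from .model_core import ModelParams
from .observables import GroundStateRegister, compute_q1_q2, q2frac

__all__ = ["TemperatureLadder", "build_ladder", "RunConfig", "RemcResult",
           "ReplicaExchange", "swap_attempt", "swap_probability", "run_remc"]


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing temperatures in units of S_LJ / k_B."""

    temperatures: tuple

    def __post_init__(self):
        t = np.asarray(self.temperatures, float)
        if t.size < 2 or np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("ladder must be >= 2 strictly increasing "
                             "positive temperatures")

    @classmethod
    def geometric(cls, t_min: float = 0.03, t_max: float = 2.5,
                  m: int = 32) -> "TemperatureLadder":
        """T_i = t_min * (t_max/t_min)^((i-1)/(m-1)); endpoints exact."""
        if not (0 < t_min < t_max) or m < 2:
            raise ValueError("need 0 < t_min < t_max and m >= 2")
        i = np.arange(m)
        t = t_min * (t_max / t_min) ** (i / (m - 1))
        t[0], t[-1] = t_min, t_max
        return cls(tuple(t))

    def __len__(self) -> int:
        return len(self.temperatures)

    def __getitem__(self, i):
        return self.temperatures[i]


def build_ladder(t_min: float, t_max: float, m: int) -> TemperatureLadder:
    return TemperatureLadder.geometric(t_min, t_max, m)


def swap_probability(t_a: float, t_b: float, e_a: float, e_b: float) -> float:
    """min(1, exp[(beta_a - beta_b)(E_a - E_b)]) for a conformation swap."""
    x = (1.0 / t_a - 1.0 / t_b) * (e_a - e_b)
    return 1.0 if x >= 0 else float(np.exp(x))


def swap_attempt(a: MCState, b: MCState,
                 rng: np.random.Generator) -> bool:
    """Attempt to exchange the conformations of two neighbouring replicas."""
    p = swap_probability(a.temperature, b.temperature, a.energy, b.energy)
    if p >= 1.0 or rng.random() < p:
        a.positions, b.positions = b.positions, a.positions
        a.energy, b.energy = b.energy, a.energy
        return True
    return False


@dataclass
class RunConfig:
    """Run configuration; defaults are the documented study conditions.

    A "sweep" is ``n`` attempted updates.  The nominal defaults
    (10^4 equilibration / 10^5 measurement sweeps) are long; tests and
    the desk-scale pipeline pass reduced values explicitly.
    """

    n: int = 30
    s_tau: float = 0.0
    t_min: float = 0.03
    t_max: float = 2.5
    n_replicas: int = 32
    swap_interval_updates: int = 400
    n_sweeps_equil: int = 10_000
    n_sweeps_measure: int = 100_000
    sample_interval: int = 1          # in sweeps
    seed: int = 0
    rd_init: float = 0.3
    displacement_weight_factor: int = 3
    tune_displacement: bool = True
    classify_samples: bool = True
    swap_enabled: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        from pathlib import Path
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib
            d = tomllib.loads(text)
        else:
            d = json.loads(text)
        return cls(**d)


@dataclass
class RemcResult:
    """Observable records, swap statistics and the ground-state register."""

    config: RunConfig
    params: ModelParams
    ladder: TemperatureLadder
    records: pd.DataFrame
    ground_state: GroundStateRegister
    swap_stats: pd.DataFrame
    acceptance: pd.DataFrame
    final_positions: list = field(default_factory=list)
    label_minima: dict = field(default_factory=dict)


class ReplicaExchange:
    """Stateful REMC run; see module docstring for the protocol."""

    def __init__(self, config: RunConfig, params: ModelParams | None = None,
                 initial: list[np.ndarray] | None = None):
        from .structure_analysis import make_random_coil

        self.config = config
        self.params = (params or ModelParams()).with_s_tau(config.s_tau)
        self.ladder = TemperatureLadder.geometric(
            config.t_min, config.t_max, config.n_replicas)
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicas + 2)
        self.swap_rng = np.random.default_rng(seeds[-2])
        init_rng = np.random.default_rng(seeds[-1])
        m = config.n_replicas
        self.replicas: list[MCState] = []
        self.schedules: list[MoveSchedule] = []
        for i in range(m):
            pos = (np.array(initial[i], float) if initial is not None
                   else make_random_coil(config.n, self.params, init_rng))
            st = MCState.from_conformation(
                pos, self.params, self.ladder[i], np.random.default_rng(seeds[i]))
            self.replicas.append(st)
            self.schedules.append(MoveSchedule(
                displacement_weight_factor=config.displacement_weight_factor,
                rd=config.rd_init))
        self.ground_state = GroundStateRegister()
        # lowest-energy sampled frame per structure label (quench candidates)
        self.label_minima: dict[str, GroundStateRegister] = {}
        self._swap_parity = 0
        self._swap_att = np.zeros(m - 1, int)
        self._swap_acc = np.zeros(m - 1, int)
        self._slot_of_conformation = list(range(m))  # replica-diffusion audit

    # -- phases ---------------------------------------------------------

    def tune(self) -> None:
        if self.config.tune_displacement:
            for st, sched in zip(self.replicas, self.schedules):
                tune_rd(st, sched)
            for st in self.replicas:
                st.n_proposed = {"disp": 0, "tor": 0}
                st.n_accepted = {"disp": 0, "tor": 0}

    def _attempt_swaps(self) -> None:
        if not self.config.swap_enabled:
            return
        start = self._swap_parity
        self._swap_parity ^= 1
        for j in range(start, len(self.replicas) - 1, 2):
            self._swap_att[j] += 1
            if swap_attempt(self.replicas[j], self.replicas[j + 1],
                            self.swap_rng):
                self._swap_acc[j] += 1
                s = self._slot_of_conformation
                s[j], s[j + 1] = s[j + 1], s[j]

    def _advance(self, n_updates_total: int, sample_hook=None) -> None:
        """Advance all replicas by a number of updates each, interleaving
        swap attempts every ``swap_interval_updates`` and sampling every
        ``sample_interval`` sweeps."""
        cfg = self.config
        n = cfg.n
        done = 0
        next_swap = cfg.swap_interval_updates
        sample_updates = cfg.sample_interval * n
        next_sample = sample_updates if sample_hook else np.inf
        while done < n_updates_total:
            target = min(next_swap, next_sample, n_updates_total)
            step = target - done
            for st, sched in zip(self.replicas, self.schedules):
                run_updates(st, sched, step)
            done = target
            if done == next_swap:
                self._attempt_swaps()
                next_swap += cfg.swap_interval_updates
            if sample_hook and done == next_sample:
                sample_hook(done // n)
                next_sample += sample_updates

    def run(self) -> RemcResult:
        cfg = self.config
        self.tune()
        self._advance(cfg.n_sweeps_equil * cfg.n)
        rows = []
        p = self.params

        if cfg.classify_samples:
            from .structure_analysis import (ClassifierThresholds, classify,
                                             detect_helix_segments)
            thresholds = ClassifierThresholds()

        def sample(sweep: int) -> None:
            for slot, st in enumerate(self.replicas):
                e = st.resync_energy()
                q1, q2 = compute_q1_q2(st.positions, p)
                row = {"sweep": sweep, "slot": slot,
                       "T": st.temperature, "E": e,
                       "q1": q1, "q2": q2, "q2frac": q2frac(q1, q2)}
                if cfg.classify_samples:
                    label = classify(st.positions, p, thresholds).label
                    row["label"] = label
                    reg = self.label_minima.setdefault(label,
                                                       GroundStateRegister())
                    reg.update(e, st.positions, sweep, st.temperature)
                rows.append(row)
                self.ground_state.update(e, st.positions, sweep,
                                         st.temperature)

        self._advance(cfg.n_sweeps_measure * cfg.n, sample_hook=sample)
        records = pd.DataFrame(rows)
        m = len(self.replicas)
        swap_stats = pd.DataFrame({
            "edge": np.arange(m - 1),
            "T_low": [self.ladder[j] for j in range(m - 1)],
            "T_high": [self.ladder[j + 1] for j in range(m - 1)],
            "attempted": self._swap_att,
            "accepted": self._swap_acc,
        })
        acceptance = pd.DataFrame({
            "slot": np.arange(m),
            "T": list(self.ladder.temperatures),
            "rd": [s.rd for s in self.schedules],
            "disp_proposed": [s.n_proposed["disp"] for s in self.replicas],
            "disp_accepted": [s.n_accepted["disp"] for s in self.replicas],
            "tor_proposed": [s.n_proposed["tor"] for s in self.replicas],
            "tor_accepted": [s.n_accepted["tor"] for s in self.replicas],
        })
        return RemcResult(cfg, p, self.ladder, records, self.ground_state,
                          swap_stats, acceptance,
                          [st.positions.copy() for st in self.replicas],
                          self.label_minima)

    def occupancy_is_bijective(self) -> bool:
        """Audit: the conformation-slot assignment is a permutation."""
        return sorted(self._slot_of_conformation) == list(range(len(self.replicas)))

    # -- checkpointing --------------------------------------------------

    def save_checkpoint(self, path) -> None:
        state = {
            "config": asdict(self.config),
            "params": self.params.to_dict(),
            "positions": [st.positions.tolist() for st in self.replicas],
            "energies": [st.energy for st in self.replicas],
            "rd": [s.rd for s in self.schedules],
            "rng_states": [st.rng.bit_generator.state for st in self.replicas],
            "swap_rng_state": self.swap_rng.bit_generator.state,
            "swap_parity": self._swap_parity,
        }
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def load_checkpoint(cls, path) -> "ReplicaExchange":
        with open(path) as fh:
            state = json.load(fh)
        cfg = RunConfig(**state["config"])
        params = ModelParams.from_dict(state["params"])
        obj = cls(cfg, params, initial=[np.array(x) for x in state["positions"]])
        for st, e, rd, rs in zip(obj.replicas, state["energies"], state["rd"],
                                 state["rng_states"]):
            st.energy = e
            st.rng.bit_generator.state = rs
        for sched, rd in zip(obj.schedules, state["rd"]):
            sched.rd = rd
        obj.swap_rng.bit_generator.state = state["swap_rng_state"]
        obj._swap_parity = state["swap_parity"]
        return obj


def run_remc(config: RunConfig, params: ModelParams | None = None,
             initial: list[np.ndarray] | None = None) -> RemcResult:
    """Build and run a replica-exchange simulation (convenience wrapper)."""
    return ReplicaExchange(config, params, initial).run()
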