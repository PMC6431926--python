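"""Conformation fixtures and structure-type classification.

The model's low-temperature states fall into a small taxonomy: random
coils, compact non-helical globules (liquid or amorphous solid), single
helices, and two- or three-helix bundles.  Frames are classified from
explicit geometric diagnostics:

* helical dihedrals — a dihedral is helical when its circular distance
  to the reference angle ``tau0`` is at most ``tol``; maximal runs of at
  least ``min_run`` consecutive helical dihedrals form helix segments;
* the split non-bonded energies ``q1`` (short range, separation <= 6
  bonds) and ``q2`` (long range, > 6 bonds), which discriminate single
  helices (|q2| ~ 0) from bundles (q2 < 0);
* the radius of gyration and contact energy, which separate extended
  coils from compact states.

Whether a compact non-helical frame is "liquid" or "amorphous solid"
is an ensemble-level statement (relative to the freezing transition)
and is resolved in :mod:`helibundle.phase_pipeline`; the frame-level
label is ``compact``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import _kernels as _k
from .model_core import (ModelParams, bond_lengths, total_energy,
                         validate_conformation)
from .observables import compute_q1_q2

__all__ = [
    "RANDOM_COIL", "COMPACT", "LIQUID", "AMORPHOUS_SOLID", "SINGLE_HELIX",
    "TWO_HELIX_BUNDLE", "THREE_HELIX_BUNDLE", "MIXED", "ORDERED_LABELS",
    "HelixSegmentation", "StructureLabel", "ClassifierThresholds",
    "detect_helix_segments", "classify", "classify_diagnostics",
    "make_ideal_helix", "make_bundle", "make_rod", "make_random_coil",
    "radius_of_gyration", "fit_helix_axis", "monomers_per_turn",
]

RANDOM_COIL = "random_coil"
COMPACT = "compact"           # frame-level: compact, non-helical
LIQUID = "liquid"             # ensemble-level refinement of COMPACT
AMORPHOUS_SOLID = "amorphous_solid"
SINGLE_HELIX = "single_helix"
TWO_HELIX_BUNDLE = "two_helix_bundle"
THREE_HELIX_BUNDLE = "three_helix_bundle"
MIXED = "mixed"

# most ordered (lowest entropy) first; used for deterministic tie-breaks
ORDERED_LABELS = [THREE_HELIX_BUNDLE, TWO_HELIX_BUNDLE, SINGLE_HELIX,
                  AMORPHOUS_SOLID, COMPACT, LIQUID, MIXED, RANDOM_COIL]


def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    d = np.mod(a - b + math.pi, 2.0 * math.pi) - math.pi
    return np.abs(d)


@dataclass(frozen=True)
class HelixSegmentation:
    """Maximal helical runs: segments[(first monomer, last monomer)]."""

    segments: tuple
    helical: np.ndarray  # per-dihedral boolean flags

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def helical_fraction(self) -> float:
        return float(self.helical.mean()) if self.helical.size else 0.0


@dataclass(frozen=True)
class ClassifierThresholds:
    """Config-exposed thresholds of the structure classifier."""

    tol: float = 0.35                # rad, helical-dihedral window around tau0
    min_run: int = 3                 # dihedrals per helix segment
    single_helix_coverage: float = 0.8
    q2_small_frac: float = 0.1       # |q2| < frac*|q1+q2| counts as "no q2"
    coil_helical_fraction: float = 0.25
    # contact energy per monomer above this marks an uncollapsed (coil)
    # frame; the default sits in the collapse region of the 30-mer
    coil_lj_per_monomer: float = -0.9


@dataclass(frozen=True)
class StructureLabel:
    label: str
    diagnostics: dict = field(default_factory=dict, compare=False)


def detect_helix_segments(pos: np.ndarray, p: ModelParams,
                          tol: float = 0.35,
                          min_run: int = 3) -> HelixSegmentation:
    """Find maximal runs of >= min_run consecutive helical dihedrals.

    A segment covering dihedrals [l0, l1] spans monomers l0 .. l1 + 3.
    Degenerate (collinear) dihedrals are counted as non-helical.
    """
    pos = np.ascontiguousarray(pos, dtype=float)
    taus = _k.dihedral_array(pos)  # NaN where degenerate
    with np.errstate(invalid="ignore"):
        helical = np.where(np.isnan(taus), False, _circ_dist(taus, p.tau0) <= tol)
    segments = []
    start = None
    for l, h in enumerate(helical.tolist() + [False]):
        if h and start is None:
            start = l
        elif not h and start is not None:
            if l - start >= min_run:
                segments.append((start, l - 1 + 3))  # monomer span
            start = None
    return HelixSegmentation(tuple(segments), helical)


def classify_diagnostics(n: int, n_segments: int, coverage: float,
                         helical_fraction: float, q1: float, q2: float,
                         thresholds: ClassifierThresholds | None = None) -> str:
    """Pure rule cascade from precomputed diagnostics (deterministic)."""
    t = thresholds or ClassifierThresholds()
    lj = q1 + q2
    q2_small = abs(q2) < t.q2_small_frac * abs(lj) if lj != 0.0 else True
    if n_segments == 1 and coverage >= t.single_helix_coverage \
            and lj < 0.0 and q2_small:
        return SINGLE_HELIX
    if n_segments == 2 and q2 < 0.0 and not q2_small:
        return TWO_HELIX_BUNDLE
    if n_segments == 3 and q2 < 0.0 and not q2_small:
        return THREE_HELIX_BUNDLE
    # no persistent ordered pattern: uncollapsed frames are coils even
    # when thermally fluctuating helical stretches are present
    if lj >= t.coil_lj_per_monomer * n:
        return RANDOM_COIL
    if helical_fraction < t.coil_helical_fraction:
        return COMPACT
    return MIXED


def classify(pos: np.ndarray, p: ModelParams,
             thresholds: ClassifierThresholds | None = None,
             seg: HelixSegmentation | None = None,
             q1: float | None = None, q2: float | None = None) -> StructureLabel:
    """Classify a single conformation into the structure taxonomy."""
    t = thresholds or ClassifierThresholds()
    pos = np.asarray(pos, float)
    n = len(pos)
    if seg is None:
        seg = detect_helix_segments(pos, p, t.tol, t.min_run)
    if q1 is None or q2 is None:
        q1, q2 = compute_q1_q2(pos, p)
    n_dihedrals = max(n - 3, 1)
    coverage = (max((b - a + 1 - 3 for a, b in seg.segments), default=0)
                / n_dihedrals)
    label = classify_diagnostics(n, seg.n_segments, coverage,
                                 seg.helical_fraction, q1, q2, t)
    diag = {
        "n_segments": seg.n_segments,
        "helical_fraction": seg.helical_fraction,
        "coverage": coverage,
        "q1": q1, "q2": q2,
        "rg": radius_of_gyration(pos),
    }
    return StructureLabel(label, diag)


# ---------------------------------------------------------------------------
# fixture generators
# ---------------------------------------------------------------------------

def _place_next(a, b, c, r, theta, tau):
    """Place d with bond length r, bond-vector angle theta, dihedral tau."""
    u = c - b
    u /= np.linalg.norm(u)
    nvec = np.cross(b - a, u)
    nn = np.linalg.norm(nvec)
    if nn < 1e-12:
        raise ValueError("cannot place from collinear frame")
    nvec /= nn
    m = np.cross(nvec, u)
    return c + r * (math.cos(theta) * u
                    + math.sin(theta) * (math.cos(tau) * m
                                         + math.sin(tau) * nvec))


def make_ideal_helix(n: int, p: ModelParams | None = None,
                     theta: float | None = None,
                     tau: float | None = None) -> np.ndarray:
    """Ideal helix: all bonds r0, all bending angles theta0, dihedrals tau0.

    Built by sequential internal-coordinate placement; with the default
    parameters the helix has ~4 monomers per turn.
    """
    p = p or ModelParams()
    if n < 4:
        raise ValueError("need n >= 4")
    theta = p.theta0 if theta is None else theta
    tau = p.tau0 if tau is None else tau
    pos = np.zeros((n, 3))
    pos[1] = (p.r0, 0.0, 0.0)
    pos[2] = pos[1] + p.r0 * np.array([math.cos(theta), math.sin(theta), 0.0])
    for i in range(3, n):
        pos[i] = _place_next(pos[i - 3], pos[i - 2], pos[i - 1],
                             p.r0, theta, tau)
    return pos


def make_rod(n: int, p: ModelParams | None = None,
             spacing: float = 1.2) -> np.ndarray:
    """Straight rod along x; default spacing puts all non-bonded pairs
    beyond the LJ cutoff while staying inside the FENE limits."""
    p = p or ModelParams()
    if not (p.r0 - p.R < spacing < p.r0 + p.R):
        raise ValueError("rod spacing violates the FENE limits")
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return pos


def _upright_helix(m: int, p: ModelParams) -> np.ndarray:
    """Ideal helix rotated so its fitted axis is +z, starting near origin."""
    pos = make_ideal_helix(m, p)
    axis, center = fit_helix_axis(pos)
    if axis @ (pos[-1] - pos[0]) < 0:
        axis = -axis
    # rotate axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = axis @ z
    if s < 1e-12:
        Rm = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        Rm = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = (pos - center) @ Rm.T
    out -= out[0]
    return out


def _min_nonbonded_distance(pos: np.ndarray) -> float:
    d2min = np.inf
    for i in range(len(pos) - 2):
        d2 = np.sum((pos[i + 2:] - pos[i]) ** 2, axis=1)
        d2min = min(d2min, d2.min())
    return math.sqrt(d2min)


def _arc_turn(a, b, n_points, outward, bond_target):
    """Points joining a to b on a circular arc bulging toward ``outward``,
    with sub-chords close to ``bond_target``; None when infeasible."""
    g = np.linalg.norm(b - a)
    nseg = n_points + 1
    if g < 1e-9:
        return None
    e1 = (b - a) / g
    e2 = outward - (outward @ e1) * e1
    if np.linalg.norm(e2) < 1e-9:
        return None
    e2 /= np.linalg.norm(e2)
    ratio = bond_target / g
    if ratio <= 1.0 / nseg + 1e-9:
        # a straight line already gives long-enough sub-bonds
        ts = np.arange(1, nseg) / nseg
        return a[None, :] + ts[:, None] * (b - a)[None, :]
    # solve sin(alpha/(2 nseg)) / sin(alpha/2) = ratio by bisection
    lo, hi = 1e-3, 2.0 * math.pi - 1e-2
    f = lambda alpha: math.sin(alpha / (2 * nseg)) / math.sin(alpha / 2) - ratio
    if f(hi) < 0:
        return None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    radius = g / (2.0 * math.sin(alpha / 2))
    center = 0.5 * (a + b) - radius * math.cos(alpha / 2) * e2
    phis = -alpha / 2 + alpha * np.arange(1, nseg) / nseg
    return (center[None, :]
            + radius * (np.sin(phis)[:, None] * e1[None, :]
                        + np.cos(phis)[:, None] * e2[None, :]))


def _assemble_bundle(n_helices, base, flipped, spacing, tilt, twist, p,
                     turn_monomers):
    """One candidate packing; returns None when a bond or clash check fails."""
    chains = []
    for j in range(n_helices):
        h = (base if j % 2 == 0 else flipped).copy()
        if j % 2 == 1:
            # azimuthal twist to vary the contact phase between helices
            ca, sa = math.cos(twist * j), math.sin(twist * j)
            h = h @ np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
            h[:, 2] += base[-1, 2] - h[0, 2]  # runs downward from the top
        h[:, 0] += j * spacing
        chains.append(h)
    parts = [chains[0]]
    for j in range(1, n_helices):
        a = parts[-1][-1]          # end of previous helix
        b = chains[j][0]           # start of next helix
        zdir = 1.0 if j % 2 == 1 else -1.0  # joints alternate top/bottom
        outward = np.array([0.0, tilt * (-1.0) ** j, zdir])
        turn = _arc_turn(a, b, turn_monomers, outward, 0.95 * p.r0)
        if turn is None:
            return None
        r = bond_lengths(np.vstack([a[None], turn, b[None]]))
        if not np.all((r > p.r0 - p.R + 1e-3) & (r < p.r0 + p.R - 1e-3)):
            return None
        parts.append(turn)
        parts.append(chains[j])
    return np.vstack(parts)


def make_bundle(n_helices: int, monomers_per_helix: int,
                p: ModelParams | None = None,
                turn_monomers: int = 3) -> np.ndarray:
    """Helix bundle fixture: ideal antiparallel helices packed side by
    side and joined by short arc-shaped turns.

    A small deterministic search over axis spacing, turn-arc height and
    helix twist keeps all bonds inside the FENE limits and all
    non-bonded pairs out of the Lennard-Jones core, then returns the
    lowest-energy candidate (i.e. the best-contacting packing).
    """
    p = p or ModelParams()
    if monomers_per_helix < 6:
        raise ValueError("need >= 6 monomers per helix for a detectable segment")
    if n_helices < 1:
        raise ValueError("need n_helices >= 1")
    if n_helices == 1:
        return make_ideal_helix(monomers_per_helix, p)
    base = _upright_helix(monomers_per_helix, p)
    flipped = base @ np.diag([1.0, -1.0, -1.0])  # proper rotation: pi about x

    best = None
    best_e = np.inf
    for spacing in np.arange(1.2, 2.01, 0.05):
        for tilt in (0.2, 0.35, 0.5, 0.7, 1.0):
            for twist in np.arange(0.0, 2 * math.pi, 0.4):
                pos = _assemble_bundle(n_helices, base, flipped, spacing,
                                       tilt, twist, p, turn_monomers)
                if pos is None:
                    continue
                if _min_nonbonded_distance(pos) < 0.99 * p.sigma:
                    continue
                e = total_energy(pos, p).e_total
                if e < best_e:
                    best, best_e = pos, e
    if best is None:
        raise ValueError("could not pack bundle without core overlap")
    validate_conformation(best, p)
    return best


def make_random_coil(n: int, p: ModelParams | None = None,
                     rng: np.random.Generator | None = None,
                     min_sep: float = 1.7) -> np.ndarray:
    """Stiff random coil: bonds r0, bending angles theta0, dihedrals
    uniform in (-pi, pi].

    This emulates the model's high-temperature ensemble, where the
    strong bending restraint pins the bond angles but the dihedrals are
    thermally disordered.  Steps bringing non-bonded monomers closer
    than ``min_sep * sigma`` are resampled (excluded-volume rejection).
    """
    p = p or ModelParams()
    rng = rng or np.random.default_rng()
    lim = (min_sep * p.sigma) ** 2
    for _ in range(200):
        pos = np.zeros((n, 3))
        pos[1] = (p.r0, 0.0, 0.0)
        pos[2] = pos[1] + p.r0 * np.array(
            [math.cos(p.theta0), math.sin(p.theta0), 0.0])
        failed = False
        for i in range(3, n):
            for _try in range(100):
                tau = float(rng.uniform(-math.pi, math.pi))
                cand = _place_next(pos[i - 3], pos[i - 2], pos[i - 1],
                                   p.r0, p.theta0, tau)
                if np.min(np.sum((pos[:i - 1] - cand) ** 2, axis=1)) > lim:
                    pos[i] = cand
                    break
            else:
                failed = True
                break
        if not failed:
            return pos
    raise RuntimeError("failed to generate a random coil")


# ---------------------------------------------------------------------------
# geometry diagnostics
# ---------------------------------------------------------------------------

def radius_of_gyration(pos: np.ndarray) -> float:
    """Root-mean-square monomer distance from the centroid."""
    pos = np.asarray(pos, float)
    return float(np.sqrt(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1))))


def fit_helix_axis(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cylinder fit: returns (unit axis, point on axis).

    Initialised from the principal component; refined by minimising the
    spread of radial distances about the axis.
    """
    pos = np.asarray(pos, float)
    center = pos.mean(0)
    X = pos - center
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    a0 = vt[0]
    th0 = math.acos(np.clip(a0[2], -1, 1))
    ph0 = math.atan2(a0[1], a0[0])

    def radial(params):
        cx, cy, cz, th, ph, r = params
        u = np.array([math.sin(th) * math.cos(ph),
                      math.sin(th) * math.sin(ph), math.cos(th)])
        d = pos - np.array([cx, cy, cz])
        perp = d - np.outer(d @ u, u)
        return np.linalg.norm(perp, axis=1) - r

    r_init = np.mean(np.linalg.norm(X - np.outer(X @ a0, a0), axis=1))
    sol = least_squares(radial, [*center, th0, ph0, r_init], method="lm")
    cx, cy, cz, th, ph, _ = sol.x
    u = np.array([math.sin(th) * math.cos(ph),
                  math.sin(th) * math.sin(ph), math.cos(th)])
    return u, np.array([cx, cy, cz])


def monomers_per_turn(pos: np.ndarray) -> float:
    """Monomers per helical turn: 2*pi over the mean per-monomer angular
    progression about the fitted helix axis."""
    pos = np.asarray(pos, float)
    u, c = fit_helix_axis(pos)
    # orthonormal frame perpendicular to the axis
    e1 = np.cross(u, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    d = pos - c
    phi = np.unwrap(np.arctan2(d @ e2, d @ e1))
    dphi = np.abs(np.diff(phi))
    return float(2.0 * math.pi / dphi.mean())


def quench(pos: np.ndarray, p: ModelParams,
           maxiter: int = 3000) -> tuple[np.ndarray, float]:
    """Local energy minimisation (T -> 0 quench) of a conformation.

    Stays within the basin of attraction of the input structure; used
    to turn sampled low-energy candidates into putative ground states.
    """
    from scipy.optimize import minimize

    n = len(pos)

    def fun(x):
        try:
            return total_energy(x.reshape(n, 3), p).e_total
        except Exception:
            return 1e12

    res = minimize(fun, np.asarray(pos, float).ravel(), method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-10})
    return res.x.reshape(n, 3), float(fun(res.x))


def anneal_and_minimize(pos: np.ndarray, p: ModelParams,
                        temperature: float = 0.05,
                        n_sweeps: int = 200,
                        seed: int = 0) -> tuple[np.ndarray, float]:
    """Short Metropolis anneal followed by local minimisation.

    Returns the relaxed conformation and its total energy.  Used to
    produce minimum-energy representatives of a structure type (e.g. the
    single helix whose pitch is measured for the monomers-per-turn
    check).
    """
    from .mc_engine import MCState, MoveSchedule, run_sweeps, tune_rd

    rng = np.random.default_rng(seed)
    state = MCState.from_conformation(pos, p, temperature, rng)
    sched = MoveSchedule(rd=0.05, rd_tuning_window_sweeps=20,
                         rd_tuning_max_iter=20)
    tune_rd(state, sched)
    run_sweeps(state, sched, n_sweeps)
    return quench(state.positions, p)
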