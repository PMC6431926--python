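"""Coarse-grained semiflexible helical-polymer model.

A linear homopolymer of N identical monomers with four energy terms:

* FENE bonds between adjacent monomers (finite extensibility, hard
  stretching limit at ``r0 ± R``),
* a cut-and-shifted 12-6 Lennard-Jones potential between non-bonded
  monomers,
* a cosine bending restraint ``1 - cos(theta - theta0)`` on the angle
  between consecutive bond vectors,
* a cosine torsion restraint ``1 - cos(tau - tau0)`` on the dihedral
  angle of each set of four consecutive monomers.

The total energy is

    E = S_FENE * sum_bonds v_FENE + S_LJ * sum_pairs v_LJ
      + S_theta * sum_angles v_bend + S_tau * sum_dihedrals v_tor

with all energies in units of ``S_LJ`` (set to 1) and lengths in units
of the reference bond length ``r0``.  The torsion strength ``S_tau`` is
the free material parameter of the model; everything else is fixed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels as _k

__all__ = [
    "ModelParams",
    "EnergyBreakdown",
    "ForbiddenBondError",
    "fene_energy",
    "lj_energy",
    "bend_energy",
    "torsion_energy",
    "bending_angle",
    "dihedral_angle",
    "bond_lengths",
    "bending_angles",
    "dihedral_angles",
    "total_energy",
    "displacement_delta",
    "pivot_delta",
    "validate_conformation",
]


class ForbiddenBondError(ValueError):
    """A bonded pair violates the FENE stretching limit ``r0 ± R``."""


def _default_R(r0: float) -> float:
    return (3.0 / 7.0) * r0


def _default_sigma(r0: float) -> float:
    return 2.0 ** (-1.0 / 6.0) * r0


@dataclass(frozen=True)
class ModelParams:
    """All constants of the four-term potential.

    The FENE term is implemented as the conventional restraint
    ``-log{1 - [(r - r0)/R]^2}``, which is zero at ``r = r0`` and
    diverges to +inf at the stretching limits, so that stretched bonds
    are penalised (``fene_sign_convention`` records this choice).

    ``vc`` is always derived from ``rc`` so that the shifted LJ
    potential vanishes continuously at the cutoff, for any ``rc``.
    """

    r0: float = 1.0
    R: float = field(default=3.0 / 7.0)
    sigma: float = field(default=2.0 ** (-1.0 / 6.0))
    rc: float = field(default=2.5 * 2.0 ** (-1.0 / 6.0))
    theta0: float = 1.4
    tau0: float = 0.873
    s_fene: float = 98.0 / 5.0
    s_lj: float = 1.0
    s_theta: float = 200.0
    s_tau: float = 0.0
    fene_sign_convention: str = "restraint"  # -log(...) >= 0

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.R <= 0 or self.sigma <= 0 or self.rc <= 0:
            raise ValueError("length parameters must be positive")
        if self.s_tau < 0:
            raise ValueError("torsion strength s_tau must be >= 0")
        if self.fene_sign_convention != "restraint":
            raise ValueError("only the 'restraint' FENE sign convention is supported")

    @property
    def vc(self) -> float:
        """LJ shift: unshifted 12-6 value at the cutoff ``rc``."""
        s6 = (self.sigma / self.rc) ** 6
        return 4.0 * (s6 * s6 - s6)

    def with_s_tau(self, s_tau: float) -> "ModelParams":
        return replace(self, s_tau=float(s_tau))

    # -- flat key-value config round trip (JSON dialect) ---------------

    def to_dict(self) -> dict:
        return {
            "r0": self.r0, "R": self.R, "sigma": self.sigma, "rc": self.rc,
            "vc": self.vc, "theta0": self.theta0, "tau0": self.tau0,
            "S_FENE": self.s_fene, "S_LJ": self.s_lj,
            "S_theta": self.s_theta, "S_tau": self.s_tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kw = {}
        alias = {"S_FENE": "s_fene", "S_LJ": "s_lj", "S_theta": "s_theta",
                 "S_tau": "s_tau"}
        for key, val in d.items():
            if key == "vc":  # derived; ignored on input
                continue
            kw[alias.get(key, key)] = float(val)
        return cls(**kw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            return cls.from_dict(tomllib.loads(text))
        return cls.from_dict(json.loads(text))

    def _tuple(self) -> tuple:
        """Scalar parameter pack consumed by the numba kernels."""
        return (self.r0, self.R, self.sigma, self.rc, self.vc,
                self.theta0, self.tau0,
                self.s_fene, self.s_lj, self.s_theta, self.s_tau)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies, each already multiplied by its scale."""

    e_fene: float
    e_lj: float
    e_bend: float
    e_tor: float

    @property
    def e_total(self) -> float:
        return self.e_fene + self.e_lj + self.e_bend + self.e_tor


# ---------------------------------------------------------------------------
# scalar potentials (unscaled, per bond / pair / angle / dihedral)
# ---------------------------------------------------------------------------

def fene_energy(r: float, p: ModelParams) -> float:
    """FENE bond restraint, zero at ``r = r0``, +inf at ``r0 ± R``."""
    x = (r - p.r0) / p.R
    if not -1.0 < x < 1.0:
        raise ForbiddenBondError(
            f"bond length {r} outside ({p.r0 - p.R}, {p.r0 + p.R})")
    return -math.log1p(-x * x)


def lj_energy(r: float, p: ModelParams) -> float:
    """Cut-and-shifted 12-6 Lennard-Jones pair energy; exactly 0 for r >= rc."""
    if r <= 0.0:
        raise ValueError("singular overlap: pair distance must be positive")
    if r >= p.rc:
        return 0.0
    s6 = (p.sigma / r) ** 6
    return 4.0 * (s6 * s6 - s6) - p.vc


def bend_energy(theta: float, p: ModelParams) -> float:
    return 1.0 - math.cos(theta - p.theta0)


def torsion_energy(tau: float, p: ModelParams) -> float:
    return 1.0 - math.cos(tau - p.tau0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def bending_angle(a, b, c) -> float:
    """Angle in [0, pi] between consecutive bond vectors (0 = straight chain)."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    u, v = b - a, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate geometry: zero-length bond")
    return float(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))


def dihedral_angle(a, b, c, d) -> float:
    """Signed dihedral in (-pi, pi], right-hand rule about the central bond.

    The cis arrangement (d on the same side of the b-c line as a, in the
    a,b,c plane) is 0; planar trans (zig-zag) is pi.
    """
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral: three collinear points")
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    return float(np.arctan2(y, n1 @ n2))


def bond_lengths(pos: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(np.asarray(pos, float), axis=0), axis=1)


def bending_angles(pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, float)
    return np.array([bending_angle(pos[k - 1], pos[k], pos[k + 1])
                     for k in range(1, len(pos) - 1)])


def dihedral_angles(pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, float)
    return np.array([dihedral_angle(*pos[l:l + 4]) for l in range(len(pos) - 3)])


def validate_conformation(pos: np.ndarray, p: ModelParams) -> np.ndarray:
    """Check shape and the hard FENE bond-length invariant; return float array."""
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("conformation must have shape (n, 3)")
    if pos.shape[0] < 4:
        raise ValueError("need at least 4 monomers to define a dihedral")
    r = bond_lengths(pos)
    bad = (r <= p.r0 - p.R) | (r >= p.r0 + p.R)
    if bad.any():
        raise ForbiddenBondError(
            f"bonds {np.flatnonzero(bad).tolist()} outside the FENE limits")
    return pos


# ---------------------------------------------------------------------------
# full and incremental energy evaluation
# ---------------------------------------------------------------------------

def total_energy(pos: np.ndarray, p: ModelParams) -> EnergyBreakdown:
    """Sum the four scaled terms over the whole conformation.

    Dihedrals with three exactly collinear points contribute 0 to the
    torsion term (a measure-zero configuration during sampling).
    """
    pos = validate_conformation(pos, p)
    e_f, e_l, e_b, e_t = _k.total_energy_terms(pos, *p._tuple()[:7])
    return EnergyBreakdown(
        e_fene=p.s_fene * e_f,
        e_lj=p.s_lj * e_l,
        e_bend=p.s_theta * e_b,
        e_tor=p.s_tau * e_t,
    )


def displacement_delta(pos: np.ndarray, i: int, new_xyz: np.ndarray,
                       p: ModelParams) -> float:
    """Energy change for moving monomer ``i`` to ``new_xyz``.

    Returns +inf when the proposal violates a FENE stretching limit
    (an automatic rejection upstream).
    """
    pos = np.ascontiguousarray(pos, dtype=float)
    return float(_k.displacement_delta(
        pos, int(i), np.asarray(new_xyz, dtype=float), *p._tuple()))


def pivot_delta(pos: np.ndarray, bond: int, phi: float, rotate_suffix: bool,
                p: ModelParams) -> tuple[float, np.ndarray]:
    """Energy change and resulting coordinates for a torsion pivot.

    All monomers on one side of ``bond`` (between monomers ``bond`` and
    ``bond + 1``) are rigidly rotated by ``phi`` about the bond axis.
    Bond lengths and bending angles are preserved exactly; exactly one
    dihedral changes.
    """
    pos = np.ascontiguousarray(pos, dtype=float)
    new = pos.copy()
    de = _k.pivot_apply(new, int(bond), float(phi), bool(rotate_suffix),
                        *p._tuple())
    return float(de), new
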