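"""Plain-text I/O: XYZ conformations/trajectories and CSV tables.

All beads carry the element tag "C"; the XYZ comment line records the
chain length, torsion strength and energy as ``key=value`` pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["format_xyz_comment", "write_xyz", "read_xyz", "write_records_csv"]


def format_xyz_comment(n: int, s_tau: float | None = None,
                       energy: float | None = None) -> str:
    parts = [f"N={n}"]
    if s_tau is not None:
        parts.append(f"S_tau={s_tau:g}")
    if energy is not None:
        parts.append(f"E={energy:.6f}")
    return " ".join(parts)


def write_xyz(path, frames, comments=None, mode: str = "w") -> None:
    """Write one conformation or a list of them as (multi-frame) XYZ."""
    frames = [np.asarray(frames, float)] if np.ndim(frames) == 2 else \
        [np.asarray(f, float) for f in frames]
    if comments is None:
        comments = [format_xyz_comment(len(f)) for f in frames]
    elif isinstance(comments, str):
        comments = [comments] * len(frames)
    with open(path, mode) as fh:
        for pos, comment in zip(frames, comments):
            fh.write(f"{len(pos)}\n{comment}\n")
            for x, y, z in pos:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> list[tuple[str, np.ndarray]]:
    """Read a (multi-frame) XYZ file; returns [(comment, positions), ...]."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1].rstrip()
        pos = np.empty((n, 3))
        for k in range(n):
            fields = lines[i + 2 + k].split()
            pos[k] = [float(v) for v in fields[1:4]]
        frames.append((comment, pos))
        i += 2 + n
    return frames


def write_records_csv(records: pd.DataFrame, path) -> None:
    cols = [c for c in ("sweep", "slot", "T", "E", "q1", "q2", "q2frac",
                        "label") if c in records.columns]
    records.to_csv(path, index=False, columns=cols)
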