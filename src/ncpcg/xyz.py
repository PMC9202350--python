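"""Multi-frame XYZ trajectory files with box metadata.

Frames are written in extended-XYZ style: the comment line carries the
orthorhombic box as ``Lattice="lx 0 0 0 ly 0 0 0 lz"`` (nm), which plain
XYZ readers simply ignore but this package round-trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_xyz", "read_xyz"]


def write_xyz(path, frames, names=None, box=None, mode="w"):
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if names is None:
        names = ["X"] * n
    with open(path, mode) as fh:
        for frame in frames:
            fh.write(f"{n}\n")
            if box is not None:
                lx, ly, lz = np.asarray(box, dtype=float)
                fh.write(f'Lattice="{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 '
                         f'{lz:.10g}" Properties=species:S:1:pos:R:3\n')
            else:
                fh.write("\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path):
    """Read all frames; returns (frames (F,N,3), names, box or None)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    names = []
    box = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if 'Lattice="' in comment and box is None:
            nums = comment.split('Lattice="')[1].split('"')[0].split()
            mat = np.array([float(x) for x in nums]).reshape(3, 3)
            box = np.diag(mat)
        frame = np.empty((n, 3))
        fnames = []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            fnames.append(parts[0])
            frame[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(frame)
        if not names:
            names = fnames
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames")
    return np.stack(frames), names, box
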