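"""Basic trajectory and log analyses.

Covers the quantities one inspects first to judge whether a simulation is
equilibrated: frame-0-referenced RMSD after optimal superposition,
per-residue RMSF about the trajectory mean, geometric hydrogen-bond counts
and the energy terms printed by an MD engine's log.

Superposition uses the Kabsch algorithm (SVD of the covariance of the
centered point sets, with the reflection branch corrected so the rotation
is always proper, det = +1).

Trajectories are plain multi-MODEL PDB files read with the package's own
PDB decoder, which keeps the analysis layer free of binary formats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system_model import read_pdb

__all__ = [
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "count_hbonds",
    "parse_energy_log",
    "read_trajectory_pdb",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
]

#: Geometric H-bond criterion defaults: donor-acceptor distance (A) and
#: minimum donor-hydrogen-acceptor angle (degrees).
HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 150.0


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference in the
    least-squares sense.  The rotation is always proper (determinant +1);
    the reflection branch of the SVD solution is folded back by negating
    the smallest singular direction.  Raises ``ValueError`` on a point
    count mismatch.  With one or two points the rotation may be degenerate
    (any rotation about the connecting axis is optimal) but the returned
    transform is still a valid minimizer.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {ref.shape} vs {mob.shape}")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    p = ref - ref_c
    q = mob - mob_c
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    fitted = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _apply(rotation: np.ndarray, translation: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def rmsd_series(
    frames: np.ndarray,
    selection: list[int] | None = None,
    align: bool = True,
) -> np.ndarray:
    """Per-frame RMSD against frame 0 over the selected atoms.

    ``frames`` is (n_frames, n_atoms, 3).  With ``align`` each frame is
    first superposed onto frame 0 using only the selection, so rigid-body
    motion does not register; without it raw displacement is measured.
    """
    frames = np.asarray(frames, dtype=float)
    if selection is None:
        selection = list(range(frames.shape[1]))
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    ref = frames[0, sel]
    out = np.empty(frames.shape[0])
    for t in range(frames.shape[0]):
        mob = frames[t, sel]
        if align:
            _, _, rmsd = kabsch_superpose(ref, mob)
            out[t] = rmsd
        else:
            out[t] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsf_per_residue(
    frames: np.ndarray,
    residue_of_atom: list,
    selection: list[int] | None = None,
    align: bool = True,
    max_iter: int = 5,
) -> dict:
    """Per-residue RMSF about the trajectory mean structure.

    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2) per atom, averaged over each
    residue's selected atoms.  Frames are iteratively superposed onto the
    running mean structure (selection atoms only) before fluctuations are
    measured, so rigid-body drift does not inflate the answer.  Requires
    at least two frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs at least two frames")
    if selection is None:
        selection = list(range(frames.shape[1]))
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")

    work = frames.copy()
    if align:
        for _ in range(max_iter):
            mean = work[:, sel].mean(axis=0)
            moved = 0.0
            for t in range(work.shape[0]):
                rot, trans, _ = kabsch_superpose(mean, work[t, sel])
                newf = _apply(rot, trans, work[t])
                moved = max(moved, float(np.abs(newf - work[t]).max()))
                work[t] = newf
            if moved < 1e-10:
                break
    mean = work.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((work - mean) ** 2, axis=2), axis=0))

    out: dict = {}
    counts: dict = {}
    for i in sel:
        res = residue_of_atom[i]
        out[res] = out.get(res, 0.0) + per_atom[i]
        counts[res] = counts.get(res, 0) + 1
    return {res: out[res] / counts[res] for res in out}


def count_hbonds(
    coords: np.ndarray,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
) -> tuple[int, list[tuple[int, int, int]]]:
    """Geometric hydrogen-bond count for one frame.

    ``donors`` holds (heavy-donor index, hydrogen index) pairs and
    ``acceptors`` heavy-acceptor indices.  A pair counts when the
    donor-acceptor distance is at most ``d_cut`` and the
    donor-hydrogen-acceptor angle at least ``angle_cut``.  Donor and
    acceptor being the same atom is skipped.  Returns the count and the
    (donor, hydrogen, acceptor) index triples.
    """
    coords = np.asarray(coords, dtype=float)
    found: list[tuple[int, int, int]] = []
    for d, h in donors:
        for a in acceptors:
            if a == d or a == h:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if dist > d_cut:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if angle >= angle_cut:
                found.append((d, h, a))
    return len(found), found


def parse_energy_log(text: str) -> pd.DataFrame:
    """Parse NAMD-style ETITLE:/ENERGY: log lines into a DataFrame.

    Columns follow the most recent ETITLE header, so a restart that prints
    a second header mid-file remaps the columns from that point on.  An
    ENERGY line before any ETITLE is an error; empty input yields an empty
    frame.
    """
    header: list[str] | None = None
    rows: list[dict] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("ETITLE:"):
            header = line.split()[1:]
        elif line.startswith("ENERGY:"):
            if header is None:
                raise ValueError(f"line {lineno}: ENERGY before any ETITLE header")
            values = line.split()[1:]
            row: dict = {}
            for key, val in zip(header, values):
                try:
                    row[key] = float(val)
                except ValueError:
                    row[key] = val
            if "TS" in row:
                row["TS"] = int(row["TS"])
            rows.append(row)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows)


def read_trajectory_pdb(text: str) -> np.ndarray:
    """Read a multi-MODEL PDB as a (n_frames, n_atoms, 3) array.

    All models must hold the same atoms in the same order.
    """
    n_models = max(1, sum(1 for line in text.splitlines() if line[:6].strip() == "MODEL"))
    frames = []
    for m in range(1, n_models + 1):
        structure = read_pdb(text, model=m)
        frames.append(np.stack([r.xyz for r in structure.records]))
    arr = np.stack(frames)
    return arr
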