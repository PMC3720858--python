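"""Conformational perturbation operators ("moves") on residue subsets.

Four move kinds drive the exploration: uniform dihedral perturbation of a
subset, endpoint-constrained loop resampling, rigid-body displacement of the
chain downstream of a loop, and whole-protein energy minimization.  All
edits are torsional, so ideal covalent geometry is preserved exactly.  Loop
moves rely on cyclic coordinate descent (CCD) closure: the loop's torsions
are swept repeatedly, each rotated by the closed-form angle that best moves
the three anchor atoms (N, CA, C of the residue just past the loop) onto
their target positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .backbone import (
    ATOMS_PER_RESIDUE,
    Conformation,
    build_backbone,
    extract_dihedrals,
    wrap_angle,
)
from . import energy as energy_mod

__all__ = [
    "MoveResult",
    "ClosureConfig",
    "dihedral_perturbation",
    "ccd_close",
    "loop_sample",
    "rigid_body_move",
    "minimization_move",
    "MOVE_KINDS",
]

MOVE_KINDS = ("dihedral", "loop", "rigid", "minimize")


@dataclass
class MoveResult:
    """Outcome of applying a move.

    On failure (``success=False``) ``conformation`` is the unmodified input.
    ``diagnostics`` carries move-specific details such as CCD sweep count
    and the final anchor RMS deviation in Angstrom.
    """

    conformation: Conformation
    kind: str
    subset_id: str | None = None
    success: bool = True
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClosureConfig:
    """CCD closure settings: anchor RMS tolerance (A), sweep budget, and the
    minimum per-sweep improvement below which CCD is considered stalled."""

    tol: float = 0.08
    max_iter: int = 200
    stall_tol: float = 1e-4


DEFAULT_CLOSURE = ClosureConfig()


def dihedral_perturbation(
    conformation: Conformation,
    subset: Sequence[int],
    max_delta: float,
    rng: np.random.Generator,
) -> MoveResult:
    """Perturb each defined torsion of ``subset`` residues (1-based) by an
    independent uniform draw from [-max_delta, +max_delta]; all other
    torsions are untouched."""
    if max_delta < 0:
        raise ValueError("max_delta must be >= 0")
    residues = sorted(set(int(r) for r in subset))
    if not residues:
        return MoveResult(conformation, "dihedral", success=False,
                          diagnostics={"reason": "empty subset"})
    dih = conformation.dihedrals.copy()
    rows = np.asarray(residues) - 1
    block = dih[rows]
    mask = np.isfinite(block)
    deltas = rng.uniform(-max_delta, max_delta, size=block.shape)
    block[mask] = wrap_angle(block[mask] + deltas[mask])
    dih[rows] = block
    new = build_backbone(conformation.sequence, dih)
    return MoveResult(new, "dihedral")


def _loop_bonds(loop: tuple[int, int]):
    """(residue, slot) pairs for the free torsions of a loop, chain order."""
    lo, hi = loop
    return [(r, j) for r in range(lo, hi + 1) for j in (0, 1)]


def _anchor_indices(loop: tuple[int, int]) -> np.ndarray:
    """Atom indices of the closure anchors: N, CA, C of residue hi+1."""
    base = ATOMS_PER_RESIDUE * ((loop[1] + 1) - 1)
    return np.array([base, base + 1, base + 2])


def _check_loop(conformation: Conformation, loop) -> tuple[int, int]:
    lo, hi = int(loop[0]), int(loop[1])
    n = conformation.n_residues
    if not (2 <= lo <= hi <= n - 1):
        raise ValueError(
            f"loop {lo}-{hi} must lie within residues 2..{n - 1} "
            "(a fixed first residue and an anchor residue after the loop are required)"
        )
    return lo, hi


@njit(cache=False)
def _ccd_sweeps(coords, bonds, anchor_idx, targets, tol, max_iter, stall_tol):
    """CCD inner loop (JIT-compiled: it dominates planner runtime).

    ``bonds`` rows are (axis_atom0, axis_atom1, first_moving_atom); each
    step rotates coords[first_moving_atom:] about the bond axis by the
    closed-form angle that best moves the anchor atoms onto ``targets``.
    Returns (sweeps_used, final anchor RMS).
    """
    n = coords.shape[0]

    def _dev(coords, anchor_idx, targets):
        s = 0.0
        for i in range(3):
            for k in range(3):
                d = coords[anchor_idx[i], k] - targets[i, k]
                s += d * d
        return math.sqrt(s / 3.0)

    dev = _dev(coords, anchor_idx, targets)
    sweeps = 0
    for sweep in range(1, max_iter + 1):
        sweeps = sweep
        for b in range(bonds.shape[0]):
            a0, a1, start = bonds[b, 0], bonds[b, 1], bonds[b, 2]
            ox, oy, oz = coords[a0, 0], coords[a0, 1], coords[a0, 2]
            ax = coords[a1, 0] - ox
            ay = coords[a1, 1] - oy
            az = coords[a1, 2] - oz
            inv = 1.0 / math.sqrt(ax * ax + ay * ay + az * az)
            ax, ay, az = ax * inv, ay * inv, az * inv
            num = 0.0
            den = 0.0
            for i in range(3):
                mx = coords[anchor_idx[i], 0] - ox
                my = coords[anchor_idx[i], 1] - oy
                mz = coords[anchor_idx[i], 2] - oz
                fx = targets[i, 0] - ox
                fy = targets[i, 1] - oy
                fz = targets[i, 2] - oz
                pm = mx * ax + my * ay + mz * az
                pf = fx * ax + fy * ay + fz * az
                rx, ry, rz = mx - pm * ax, my - pm * ay, mz - pm * az
                gx, gy, gz = fx - pf * ax, fy - pf * ay, fz - pf * az
                num += ((ay * rz - az * ry) * gx
                        + (az * rx - ax * rz) * gy
                        + (ax * ry - ay * rx) * gz)
                den += rx * gx + ry * gy + rz * gz
            if num == 0.0 and den == 0.0:
                continue
            ang = math.atan2(num, den)
            c = math.cos(ang)
            s = math.sin(ang)
            for idx in range(start, n):
                bx = coords[idx, 0] - ox
                by = coords[idx, 1] - oy
                bz = coords[idx, 2] - oz
                crx = ay * bz - az * by
                cry = az * bx - ax * bz
                crz = ax * by - ay * bx
                dot = (bx * ax + by * ay + bz * az) * (1.0 - c)
                coords[idx, 0] = bx * c + crx * s + dot * ax + ox
                coords[idx, 1] = by * c + cry * s + dot * ay + oy
                coords[idx, 2] = bz * c + crz * s + dot * az + oz
        new_dev = _dev(coords, anchor_idx, targets)
        if new_dev <= tol or dev - new_dev < stall_tol:
            return sweeps, new_dev
        dev = new_dev
    return sweeps, dev


def ccd_close(
    conformation: Conformation,
    loop,
    anchor_targets: np.ndarray,
    tol: float = DEFAULT_CLOSURE.tol,
    max_iter: int = DEFAULT_CLOSURE.max_iter,
    stall_tol: float = DEFAULT_CLOSURE.stall_tol,
) -> MoveResult:
    """Drive the loop's anchor atoms onto ``anchor_targets`` by CCD.

    Sweeps the loop torsions in chain order; each torsion is rotated by the
    closed-form angle minimizing the summed squared distance of the three
    anchor atoms to their targets.  Success means RMS anchor deviation
    <= tol within the sweep budget; on failure the input is returned
    unmodified.  Torsions outside the loop are unchanged (the chain
    downstream of the loop rides rigidly with the anchor residue).
    """
    lo, hi = _check_loop(conformation, loop)
    targets = np.asarray(anchor_targets, dtype=float)
    if targets.shape != (3, 3) or not np.isfinite(targets).all():
        raise ValueError("anchor_targets must be a finite (3, 3) array")
    anchor_idx = _anchor_indices((lo, hi))
    coords = conformation.coords.copy()

    def deviation() -> float:
        return float(np.sqrt(np.mean((coords[anchor_idx] - targets) ** 2) * 3.0))

    dev = deviation()
    sweeps = 0
    if dev <= tol:
        return MoveResult(conformation, "loop",
                          diagnostics={"sweeps": 0, "anchor_rms": dev})
    bond_rows = np.array(
        [
            (base, base + 1, base + 2) if j == 0 else (base + 1, base + 2, base + 3)
            for r, j in _loop_bonds((lo, hi))
            for base in (ATOMS_PER_RESIDUE * (r - 1),)
        ],
        dtype=np.int64,
    )
    sweeps, dev = _ccd_sweeps(
        coords, bond_rows, anchor_idx.astype(np.int64), targets,
        float(tol), int(max_iter), float(stall_tol),
    )

    diagnostics = {"sweeps": sweeps, "anchor_rms": dev}
    if dev > tol:
        return MoveResult(conformation, "loop", success=False, diagnostics=diagnostics)
    closed = Conformation(conformation.sequence,
                          conformation.dihedrals.copy(), coords)
    measured = extract_dihedrals(closed)
    for r, j in _loop_bonds((lo, hi)):
        closed.dihedrals[r - 1, j] = measured[r - 1, j]
    return MoveResult(closed, "loop", diagnostics=diagnostics)


def _as_loops(loop) -> list[tuple[int, int]]:
    if len(loop) == 2 and all(np.isscalar(x) for x in loop):
        return [(int(loop[0]), int(loop[1]))]
    return [(int(lo), int(hi)) for lo, hi in loop]


def loop_sample(
    conformation: Conformation,
    loop,
    rng: np.random.Generator,
    closure: ClosureConfig = DEFAULT_CLOSURE,
) -> MoveResult:
    """Resample a loop (or a collection of loops) with endpoints held fixed.

    Records the current anchor positions, draws all loop torsions uniformly
    at random, and CCD-closes back onto the recorded anchors, so the chain
    outside the loops stays put (to within the closure tolerance).  For a
    collection, the loops are closed sequentially in random order and the
    move succeeds only if every closure succeeds; otherwise the input is
    returned unmodified.
    """
    loops = _as_loops(loop)
    for lo, hi in loops:
        if hi - lo + 1 < 3:
            return MoveResult(
                conformation, "loop", success=False,
                diagnostics={"reason": f"loop {lo}-{hi} interior shorter than 3"},
            )
        _check_loop(conformation, (lo, hi))
    order = list(rng.permutation(len(loops)))
    anchors = {i: conformation.coords[_anchor_indices(loops[i])].copy()
               for i in order}
    current = conformation
    diag = {"loops": len(loops)}
    for i in order:
        lo, hi = loops[i]
        dih = current.dihedrals.copy()
        for r, j in _loop_bonds((lo, hi)):
            if np.isfinite(dih[r - 1, j]):
                dih[r - 1, j] = rng.uniform(-180.0, 180.0)
        randomized = build_backbone(current.sequence, dih)
        res = ccd_close(randomized, (lo, hi), anchors[i],
                        closure.tol, closure.max_iter, closure.stall_tol)
        diag[f"loop_{lo}_{hi}"] = res.diagnostics
        if not res.success:
            return MoveResult(conformation, "loop", success=False, diagnostics=diag)
        current = res.conformation
    return MoveResult(current, "loop", diagnostics=diag)


def _random_rigid_transform(anchors, max_disp, max_rot, rng):
    """Random proper rotation (<= max_rot deg, about the anchor centroid)
    plus a random translation of norm <= max_disp."""
    centroid = anchors.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rot)) if max_rot > 0 else 0.0
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    if max_disp > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = direction * rng.uniform(0.0, max_disp)
    else:
        t = np.zeros(3)
    return (anchors - centroid) @ R.T + centroid + t


def rigid_body_move(
    conformation: Conformation,
    loop,
    max_disp: float = 1.0,
    max_rot: float = 5.0,
    rng: np.random.Generator | None = None,
    closure: ClosureConfig = DEFAULT_CLOSURE,
) -> MoveResult:
    """Displace the chain downstream of a loop as a rigid body.

    Samples a small random rigid transform of the loop's anchor atoms and
    CCD-closes the loop onto the transformed targets.  Because everything
    past the loop rides rigidly with the anchors, a successful closure moves
    the entire downstream domain by (approximately) the sampled transform
    while the upstream chain is untouched.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = _check_loop(conformation, loop)
    if hi - lo + 1 < 3:
        return MoveResult(conformation, "rigid", success=False,
                          diagnostics={"reason": "loop interior shorter than 3"})
    anchors = conformation.coords[_anchor_indices((lo, hi))]
    targets = _random_rigid_transform(anchors, max_disp, max_rot, rng)
    res = ccd_close(conformation, (lo, hi), targets,
                    closure.tol, closure.max_iter, closure.stall_tol)
    return MoveResult(res.conformation, "rigid", success=res.success,
                      diagnostics=res.diagnostics)


def minimization_move(
    conformation: Conformation,
    energy_fn,
    subset=None,
    max_iters: int = 15,
    step: float = 5.0,
) -> MoveResult:
    """Whole-protein (or subset) greedy energy minimization; always succeeds."""
    out = energy_mod.minimize(conformation, energy_fn, subset=subset,
                              max_iters=max_iters, step=step)
    return MoveResult(out, "minimize")
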