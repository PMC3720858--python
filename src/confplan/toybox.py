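"""Synthetic test systems with known conformational mechanisms.

Real conformational-transition benchmarks (hinge-bending lectins, multi-loop
periplasmic binding proteins) need external structure downloads; these
generators build small analogues from scratch so the whole pipeline —
schema, moves, planner, analysis — can be exercised end to end.  A hinge
toy is a helix-loop-helix whose two states differ only in the central loop
torsions; a tri-loop toy interleaves rigid helical blocks with three loops
such that the even-numbered blocks (one "domain") can move relative to the
odd-numbered blocks only through coordinated changes of all three loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import Conformation, build_backbone, wrap_angle
from .energy import clash_energy
from .moves import ccd_close

__all__ = ["ToyProblem", "make_hinge_toy", "make_triloop_toy", "make_decoys"]

HELIX_PHI_PSI = (-57.0, -47.0)  # canonical alpha-helix region
LOOP_PHI_PSI = (-120.0, 120.0)  # extended / polyproline-ish loop seed


@dataclass
class ToyProblem:
    """A start/goal conformation pair with a known mechanism.

    ``active_residues`` is the designed mechanism (the residues whose
    torsions differ between the states); ``energy_threshold`` is a
    feasibility cutoff under which both endpoints are valid.
    """

    start: Conformation
    goal: Conformation
    ss: str
    active_residues: frozenset[int]
    energy_threshold: float

    def __post_init__(self) -> None:
        assert self.start.sequence == self.goal.sequence
        assert len(self.ss) == self.start.n_residues


def _jittered(base: tuple[float, float], n: int, rng, jitter: float = 8.0):
    """n (phi, psi) rows around a Ramachandran anchor with uniform jitter."""
    out = np.tile(base, (n, 1)).astype(float)
    out += rng.uniform(-jitter, jitter, size=(n, 2))
    return out


def make_hinge_toy(
    helix_len: int = 8,
    loop_len: int = 5,
    hinge_delta: float = 40.0,
    seed: int = 0,
    energy_threshold: float = 5.0,
) -> ToyProblem:
    """Helix-loop-helix with a central hinge.

    The goal state equals the start except that every torsion of the
    central loop is shifted by ``hinge_delta`` degrees, swinging the second
    helix as a rigid arm.  Both states are verified clash-free under the
    default soft-sphere energy; if the random jitter produces a clash the
    problem is redrawn (up to 10 attempts).
    """
    if helix_len < 3 or loop_len < 3:
        raise ValueError("helix and loop lengths must be >= 3")
    n_res = 2 * helix_len + loop_len
    seq = "A" * n_res
    ss = "H" * helix_len + "L" * loop_len + "H" * helix_len
    loop_lo, loop_hi = helix_len + 1, helix_len + loop_len
    rng = np.random.default_rng(seed)
    for _ in range(10):
        dih = np.vstack([
            _jittered(HELIX_PHI_PSI, helix_len, rng),
            _jittered(LOOP_PHI_PSI, loop_len, rng),
            _jittered(HELIX_PHI_PSI, helix_len, rng),
        ])
        start = build_backbone(seq, dih)
        goal_dih = dih.copy()
        goal_dih[loop_lo - 1:loop_hi] = wrap_angle(
            goal_dih[loop_lo - 1:loop_hi] + hinge_delta
        )
        goal = build_backbone(seq, goal_dih)
        e_start = clash_energy(start)
        e_goal = clash_energy(goal)
        if e_start == 0.0 and e_goal == 0.0:
            start.energy, goal.energy = e_start, e_goal
            return ToyProblem(
                start, goal, ss,
                frozenset(range(loop_lo, loop_hi + 1)),
                energy_threshold,
            )
    raise RuntimeError(
        "could not generate a clash-free hinge problem in 10 attempts"
    )


def _anchor_atoms(conf: Conformation, residue: int) -> np.ndarray:
    base = 3 * (residue - 1)
    return conf.coords[base:base + 3].copy()


def make_triloop_toy(
    block_len: int = 6,
    loop_len: int = 4,
    rotation: float = 5.0,
    seed: int = 0,
    energy_threshold: float = 5.0,
) -> ToyProblem:
    """Four helical blocks joined by three loops, two interleaved domains.

    Domain A is blocks 1 and 3, domain B is blocks 2 and 4.  The goal state
    rotates domain B by ``rotation`` degrees relative to domain A.  Because
    the blocks alternate along the chain, realizing this motion requires
    simultaneous, coordinated closure of all three loops — which is exactly
    how the goal is generated: loop 1 is CCD-closed onto rotated anchors,
    loop 2 back onto the original anchors, loop 3 onto rotated anchors
    again.  Non-loop torsions are identical between the states.  Closure
    failure during generation raises.
    """
    if block_len < 3 or loop_len < 3:
        raise ValueError("block and loop lengths must be >= 3")
    rng = np.random.default_rng(seed)
    n_res = 4 * block_len + 3 * loop_len
    seq = "A" * n_res
    ss_parts, dih_parts, loops = [], [], []
    pos = 0
    for b in range(4):
        ss_parts.append("H" * block_len)
        dih_parts.append(_jittered(HELIX_PHI_PSI, block_len, rng))
        pos += block_len
        if b < 3:
            loops.append((pos + 1, pos + loop_len))
            ss_parts.append("L" * loop_len)
            dih_parts.append(_jittered(LOOP_PHI_PSI, loop_len, rng))
            pos += loop_len
    ss = "".join(ss_parts)
    for attempt in range(10):
        start = build_backbone(seq, np.vstack(dih_parts))
        if clash_energy(start) == 0.0:
            break
        dih_parts = [part + rng.uniform(-4, 4, size=part.shape)
                     for part in dih_parts]
    else:
        raise RuntimeError("could not generate a clash-free tri-loop start")

    # rigid transform for domain B: rotation about the structure centroid
    # (minimizes the lever arm at every loop) around a random axis; if the
    # coordinated closure fails, redraw the axis and try again
    anchors0 = [_anchor_atoms(start, hi + 1) for _, hi in loops]
    pivot = start.coords.mean(axis=0)
    ang = np.radians(rotation)
    tol = 0.05
    current = None
    for _ in range(8):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        transform = lambda pts: (pts - pivot) @ R.T + pivot
        current = start
        for k, (lo, hi) in enumerate(loops):
            targets = transform(anchors0[k]) if k % 2 == 0 else anchors0[k]
            res = ccd_close(current, (lo, hi), targets, tol=tol,
                            max_iter=200, stall_tol=1e-5)
            # greedy CCD can stall in a local minimum; restart from fully
            # randomized loop torsions until the closure lands
            for _ in range(40):
                if res.success:
                    break
                dih = current.dihedrals.copy()
                dih[lo - 1:hi] = rng.uniform(-180.0, 180.0,
                                             size=dih[lo - 1:hi].shape)
                res = ccd_close(build_backbone(seq, dih), (lo, hi), targets,
                                tol=tol, max_iter=200, stall_tol=1e-5)
            if not res.success:
                current = None
                break
            current = res.conformation
        if current is not None:
            break
    if current is None:
        raise RuntimeError(
            "coordinated tri-loop closure failed during goal generation"
        )
    goal = build_backbone(seq, current.dihedrals)
    e_goal = clash_energy(goal)
    if e_goal > energy_threshold:
        raise RuntimeError("generated tri-loop goal exceeds the energy threshold")
    start.energy = clash_energy(start)
    goal.energy = e_goal
    active = frozenset(r for lo, hi in loops for r in range(lo, hi + 1))
    return ToyProblem(start, goal, ss, active, energy_threshold)


def make_decoys(
    conformation: Conformation,
    n: int,
    sigma: float,
    seed: int = 0,
) -> list[Conformation]:
    """n copies with independent Gaussian torsion noise of scale sigma
    (degrees), wrapped; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        dih = conformation.dihedrals.copy()
        mask = np.isfinite(dih)
        dih[mask] = wrap_angle(dih[mask] + rng.normal(0.0, sigma, size=mask.sum()))
        out.append(build_backbone(conformation.sequence, dih))
    return out
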