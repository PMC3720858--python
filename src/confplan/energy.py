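"""Pluggable energy evaluation with a built-in soft-sphere clash score.

Any callable ``Conformation -> float`` (deterministic, lower is better) can
serve as an energy function; the planner only ever compares the score to a
user-chosen feasibility threshold.  The built-in score penalizes steric
overlap between backbone atoms quadratically and is zero for clash-free
structures, which makes "energy <= threshold" a simple excluded-volume
feasibility test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import math

import numpy as np
from numba import njit

from .backbone import Conformation, build_backbone, wrap_angle

__all__ = ["EnergyParams", "EnergyFunction", "clash_energy", "is_feasible", "minimize"]

EnergyFunction = Callable[[Conformation], float]


@dataclass(frozen=True)
class EnergyParams:
    """Soft-sphere parameters.

    sigma: contact radius per backbone atom (Angstrom); two atoms clash when
    their distance falls below sigma_i + sigma_j.  k: stiffness of the
    quadratic penalty (score units / A^2).  exclusion: pairs within this many
    covalent bonds along the backbone contribute nothing (covalently forced
    contacts must not dominate).  cutoff: neighbor search radius; must cover
    the largest possible overlap (cutoff >= 2 sigma).
    """

    sigma: float = 1.7
    k: float = 1.0
    # depth 4 excludes 1-5 pairs: with a uniform 1.7 A radius the C(i)-N(i+2)
    # contact of an ideal alpha-helix sits at ~3.27 A, and a depth-3 exclusion
    # would brand every helix a clash
    exclusion: int = 4
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.k <= 0:
            raise ValueError("sigma and k must be positive")
        if self.cutoff < 2 * self.sigma:
            raise ValueError("cutoff must be at least 2*sigma")


DEFAULT_ENERGY_PARAMS = EnergyParams()


def clash_energy(
    conformation: Conformation, params: EnergyParams = DEFAULT_ENERGY_PARAMS
) -> float:
    """Soft-sphere clash score: sum of k*(2 sigma - d)^2 over overlapping pairs.

    The backbone is a linear chain (N-CA-C-N-...), so the covalent bond
    count between atoms i and j is exactly |i - j|; pairs with
    |i - j| <= exclusion are skipped.
    """
    xyz = conformation.coords
    if xyz is None or len(xyz) == 0:
        raise ValueError("conformation has no coordinates")
    if len(xyz) <= params.exclusion + 1:
        return 0.0
    return float(
        _clash_sum(xyz, 2.0 * params.sigma, params.k, params.exclusion)
    )


@njit(cache=False)
def _clash_sum(xyz, contact, k, exclusion):
    n = xyz.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + exclusion + 1, n):
            dx = xyz[i, 0] - xyz[j, 0]
            dy = xyz[i, 1] - xyz[j, 1]
            dz = xyz[i, 2] - xyz[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < contact:
                ov = contact - d
                total += ov * ov
    return k * total


def make_clash_energy(params: EnergyParams = DEFAULT_ENERGY_PARAMS) -> EnergyFunction:
    """Bind parameters into a Conformation -> score callable."""
    return lambda conf: clash_energy(conf, params)


def is_feasible(
    conformation: Conformation, energy_fn: EnergyFunction, threshold: float
) -> bool:
    """True iff energy(conformation) <= threshold; caches the score."""
    e = float(energy_fn(conformation))
    conformation.energy = e
    return e <= threshold


def minimize(
    conformation: Conformation,
    energy_fn: EnergyFunction,
    subset=None,
    max_iters: int = 50,
    step: float = 5.0,
) -> Conformation:
    """Greedy derivative-free coordinate descent over backbone torsions.

    Cycles over the defined (phi, psi) of ``subset`` residues (1-based; all
    residues when None), trying +/-step for each and keeping the best
    non-worsening change.  After a full pass with no improvement the step is
    halved.  ``max_iters`` counts full passes.  The returned conformation
    never has higher energy than the input; torsions outside the subset are
    untouched.  Deterministic.
    """
    if max_iters < 0:
        raise ValueError("max_iters must be >= 0")
    best = conformation.copy()
    e_best = float(energy_fn(best))
    best.energy = e_best
    if max_iters == 0:
        return best
    n_res = best.n_residues
    if subset is None:
        residues = range(1, n_res + 1)
    else:
        residues = sorted(set(int(r) for r in subset))
    slots = [
        (r - 1, j)
        for r in residues
        for j in (0, 1)
        if 1 <= r <= n_res and np.isfinite(best.dihedrals[r - 1, j])
    ]
    if not slots:
        return best
    cur_step = float(step)
    dih = best.dihedrals
    for _ in range(max_iters):
        improved = False
        for i, j in slots:
            orig = dih[i, j]
            trial_best, e_trial_best = None, e_best
            for delta in (cur_step, -cur_step):
                dih[i, j] = wrap_angle(orig + delta)
                cand = build_backbone(best.sequence, dih)
                e = float(energy_fn(cand))
                if e < e_trial_best:
                    trial_best, e_trial_best = dih[i, j], e
            if trial_best is not None:
                dih[i, j] = trial_best
                e_best = e_trial_best
                improved = True
            else:
                dih[i, j] = orig
        if not improved:
            cur_step *= 0.5
            if cur_step < 1e-3:
                break
    out = build_backbone(best.sequence, dih)
    out.energy = e_best
    return out
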