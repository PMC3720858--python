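"""Post-hoc analysis of exploration output.

Torsional activity profiles locate the residues that do the mechanical work
along a transition path (cumulative absolute wrapped torsion change); PCA
of superposed Cartesian coordinates gives a 2D conformational landscape;
goal-distance traces and basin centroids summarize directed runs.  All
operations are pure: inputs are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import Conformation, build_backbone, superpose_rmsd, wrap_angle

__all__ = [
    "TorsionalActivityProfile",
    "Embedding2D",
    "torsional_activity",
    "pca_embed",
    "goal_distance_trace",
    "basin_centroid",
]


@dataclass
class TorsionalActivityProfile:
    """Per-residue cumulative angular change (degrees) along a path."""

    activity: np.ndarray  # shape (n_residues,)

    def top_residues(self, k: int = 10) -> list[int]:
        """1-based indices of the k most torsionally active residues."""
        order = np.argsort(self.activity)[::-1][:k]
        return [int(i) + 1 for i in order]


def torsional_activity(path: list[Conformation]) -> TorsionalActivityProfile:
    """Cumulative residue-wise torsional change along a path.

    For residue i, D_i = sum over consecutive path steps k of
    |wrap(phi_{i,k+1} - phi_{i,k})| + |wrap(psi_{i,k+1} - psi_{i,k})|;
    undefined terminal torsions contribute nothing.  Differences are
    wrapped, so a step from 179 to -179 degrees counts 2, not 358.
    """
    if len(path) < 1:
        raise ValueError("path must contain at least one conformation")
    n_res = path[0].n_residues
    for conf in path:
        if conf.n_residues != n_res:
            raise ValueError("inconsistent residue counts along path")
    D = np.zeros(n_res)
    for prev, cur in zip(path, path[1:]):
        diff = cur.dihedrals - prev.dihedrals
        diff = np.abs(wrap_angle(np.where(np.isfinite(diff), diff, 0.0)))
        D += diff.sum(axis=1)
    return TorsionalActivityProfile(D)


@dataclass
class Embedding2D:
    """2D PCA landscape: per-conformation coordinates and the explained
    variance fractions of the two components."""

    points: np.ndarray  # shape (n_conformations, 2)
    explained_variance: tuple[float, float]


def pca_embed(
    conformations: list[Conformation],
    reference: Conformation,
    superpose_atoms: str = "ca",
) -> Embedding2D:
    """PCA of Cartesian backbone coordinates after superposition.

    Each conformation is Kabsch-superposed onto ``reference`` (CA atoms by
    default), the full backbone coordinates are flattened and mean-centered,
    and the top two principal components are kept.  Global rigid placement
    of the inputs therefore cannot influence the embedding.  Degenerate
    input (all conformations identical) maps to the origin with explained
    variance reported as (0, 0).
    """
    from sklearn.decomposition import PCA

    if len(conformations) < 2:
        raise ValueError("need at least two conformations")
    rows = []
    for conf in conformations:
        if conf.coords.shape != reference.coords.shape:
            raise ValueError("all conformations must share the atom count")
        _, (R, t) = superpose_rmsd(conf, reference, atoms=superpose_atoms)
        rows.append((conf.coords @ R.T + t).ravel())
    X = np.asarray(rows)
    X = X - X.mean(axis=0)
    if float(np.abs(X).max()) < 1e-9:
        return Embedding2D(np.zeros((len(rows), 2)), (0.0, 0.0))
    pca = PCA(n_components=2)
    pts = pca.fit_transform(X)
    ev = pca.explained_variance_ratio_
    return Embedding2D(pts, (float(ev[0]), float(ev[1]) if len(ev) > 1 else 0.0))


def goal_distance_trace(path: list[Conformation], goal: Conformation) -> np.ndarray:
    """CA-RMSD (after optimal superposition) of each path step to the goal."""
    if not path:
        raise ValueError("empty path")
    return np.array([superpose_rmsd(c, goal, atoms="ca")[0] for c in path])


def basin_centroid(
    conformations: list[Conformation],
    energy_window: float | None = None,
) -> Conformation:
    """Representative conformation of a low-energy basin.

    Selects conformations whose cached energy is <= ``energy_window`` (all
    of them when None), takes the circular mean of each torsion, and rebuilds
    the backbone through the kinematics so the result has ideal geometry.
    """
    pool = conformations
    if energy_window is not None:
        pool = [c for c in conformations
                if c.energy is not None and c.energy <= energy_window]
    if not pool:
        raise ValueError("no conformations within the energy window")
    stack = np.array([c.dihedrals for c in pool])  # (m, n_res, 2), radians below
    rad = np.radians(stack)
    defined = np.isfinite(stack).any(axis=0)
    sin_sum = np.where(np.isfinite(rad), np.sin(rad), 0.0).sum(axis=0)
    cos_sum = np.where(np.isfinite(rad), np.cos(rad), 0.0).sum(axis=0)
    mean = np.degrees(np.arctan2(sin_sum, cos_sum))
    mean[~defined] = np.nan
    return build_backbone(pool[0].sequence, mean)
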