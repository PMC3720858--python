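"""Expansive tree search over conformation space (KPIECE-style).

The planner grows a tree of energetically feasible conformations.  Sampling
density is estimated in a random 2D projection of the torsions: each
conformation's defined (phi, psi) angles are mapped to the vector of their
cosines and sines, projected with a fixed random orthonormal 2x2n matrix,
and binned on a regular grid.  Non-empty cells with at least one empty
8-neighbor are "exterior" (the frontier); cell selection is heavily biased
toward exterior cells, and within a class a cell is chosen with probability
inversely proportional to its occupancy.  Each iteration (1) selects a
cell, (2) selects a conformation uniformly from it, (3) applies a random
schema move, and (4) accepts the result iff its energy is at or below the
feasibility threshold.  With a goal conformation set, a small fraction of
moves instead step every torsion toward the goal along the shortest arc
(directed search).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .backbone import (
    Conformation,
    build_backbone,
    defined_dihedrals,
    dihedral_distance,
    extract_dihedrals,
    n_defined,
    wrap_angle,
)
from .energy import is_feasible
from .moves import (
    ClosureConfig,
    dihedral_perturbation,
    loop_sample,
    minimization_move,
    rigid_body_move,
)
from .schema import Schema, contiguous_runs, sample_move

__all__ = [
    "ProjectionMatrix",
    "DensityGrid",
    "TreeNode",
    "ExplorationTree",
    "PlannerConfig",
    "make_projection",
    "project",
    "cell_index",
    "select_cell",
    "explore",
    "extract_path",
]

_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


@dataclass(frozen=True)
class ProjectionMatrix:
    """Random orthonormal 2 x 2n projection of the torsion cos/sin vector."""

    matrix: np.ndarray
    seed: int

    @property
    def n_dihedrals(self) -> int:
        return self.matrix.shape[1] // 2


def make_projection(n: int, seed: int) -> ProjectionMatrix:
    """Draw M ~ N(0,1) of shape 2 x 2n, normalize row 1, Gram-Schmidt and
    normalize row 2.  Deterministic per seed; degenerate draws are redrawn."""
    if n < 1:
        raise ValueError("need at least one torsion")
    rng = np.random.default_rng(seed)
    while True:
        m = rng.normal(size=(2, 2 * n))
        r0 = np.linalg.norm(m[0])
        if r0 < 1e-12:
            continue
        m[0] /= r0
        m[1] -= (m[1] @ m[0]) * m[0]
        r1 = np.linalg.norm(m[1])
        if r1 < 1e-12:
            continue
        m[1] /= r1
        return ProjectionMatrix(m, seed)


def project(M: ProjectionMatrix, dihedrals: np.ndarray) -> np.ndarray:
    """Project torsions (degrees, NaN = undefined) to a 2D point via the
    cos/sin feature vector (cos t1, sin t1, ..., cos tn, sin tn)."""
    angles = np.radians(defined_dihedrals(np.asarray(dihedrals, float)))
    if len(angles) != M.n_dihedrals:
        raise ValueError(
            f"projection expects {M.n_dihedrals} defined torsions, got {len(angles)}"
        )
    v = np.empty(2 * len(angles))
    v[0::2] = np.cos(angles)
    v[1::2] = np.sin(angles)
    return M.matrix @ v


def cell_index(point, cell_size: float) -> tuple[int, int]:
    """Half-open grid cell containing a 2D point: floor(point / size)."""
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    return (
        int(np.floor(point[0] / cell_size)),
        int(np.floor(point[1] / cell_size)),
    )


class DensityGrid:
    """2D occupancy grid with incremental interior/exterior classification.

    A non-empty cell is *exterior* iff at least one of its 8 neighbors is
    empty; otherwise it is *interior*.  Flags and per-cell occupancies are
    maintained incrementally in flat arrays (cell selection happens every
    planner iteration); ``reclassify`` recomputes the flags from scratch as
    a verification oracle.
    """

    def __init__(self, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell size must be positive")
        self.cell_size = float(cell_size)
        self.cells: dict[tuple[int, int], list[int]] = {}
        self.selection_counts: dict[tuple[int, int], int] = {}
        self._pos: dict[tuple[int, int], int] = {}
        self._cell_list: list[tuple[int, int]] = []
        self._counts = np.zeros(64)
        self._is_ext = np.zeros(64, dtype=bool)

    @property
    def exterior(self) -> dict[tuple[int, int], bool]:
        """Current interior/exterior flag per non-empty cell."""
        return {c: bool(self._is_ext[i]) for c, i in self._pos.items()}

    def insert(self, node_id: int, point) -> tuple[int, int]:
        cell = cell_index(point, self.cell_size)
        if cell not in self.cells:
            self.cells[cell] = [node_id]
            i = len(self._cell_list)
            if i == len(self._counts):
                self._counts = np.concatenate([self._counts, np.zeros(i)])
                self._is_ext = np.concatenate(
                    [self._is_ext, np.zeros(i, dtype=bool)]
                )
            self._pos[cell] = i
            self._cell_list.append(cell)
            self._counts[i] = 1.0
            self._is_ext[i] = self._compute_exterior(cell)
            for di, dj in _NEIGHBORS:
                nb = (cell[0] + di, cell[1] + dj)
                j = self._pos.get(nb)
                if j is not None:
                    self._is_ext[j] = self._compute_exterior(nb)
        else:
            self.cells[cell].append(node_id)
            self._counts[self._pos[cell]] += 1.0
        return cell

    def _compute_exterior(self, cell) -> bool:
        return any(
            (cell[0] + di, cell[1] + dj) not in self.cells for di, dj in _NEIGHBORS
        )

    def reclassify(self) -> dict[tuple[int, int], bool]:
        """Brute-force exterior flags (verification oracle)."""
        return {c: self._compute_exterior(c) for c in self.cells}

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.cells.values())


def select_cell(
    grid: DensityGrid, rng: np.random.Generator, p_exterior: float = 0.75
) -> tuple[int, int]:
    """Choose a grid cell: with probability ``p_exterior`` from the exterior
    class (falling back to the other class when one is empty), then within
    the class with probability inversely proportional to occupancy."""
    m = len(grid._cell_list)
    if m == 0:
        raise ValueError("empty grid")
    ext_mask = grid._is_ext[:m]
    use_ext = rng.random() < p_exterior
    mask = ext_mask if use_ext else ~ext_mask
    if not mask.any():
        mask = ~mask
    weights = np.where(mask, 1.0 / grid._counts[:m], 0.0)
    cell = grid._cell_list[int(rng.choice(m, p=weights / weights.sum()))]
    grid.selection_counts[cell] = grid.selection_counts.get(cell, 0) + 1
    return cell


@dataclass
class TreeNode:
    """One accepted conformation: provenance, score, and grid placement."""

    id: int
    parent: int | None
    conformation: Conformation
    subset_id: str | None
    move_kind: str | None
    energy: float
    point: np.ndarray
    cell: tuple[int, int]


@dataclass
class ExplorationTree:
    nodes: list[TreeNode]
    grid: DensityGrid
    projection: ProjectionMatrix
    goal_reached: int | None = None
    iterations: int = 0

    def save_jsonl(self, path) -> None:
        """Archive the tree, one node per line."""
        with open(path, "w") as fh:
            for node in self.nodes:
                fh.write(json.dumps({
                    "id": node.id,
                    "parent": node.parent,
                    "move": node.move_kind,
                    "subset": node.subset_id,
                    "energy": node.energy,
                    "dihedrals": [None if not np.isfinite(x) else round(float(x), 6)
                                  for x in node.conformation.dihedrals.ravel()],
                    "point": [float(node.point[0]), float(node.point[1])],
                }) + "\n")


@dataclass
class PlannerConfig:
    """Exploration settings.

    energy_threshold: feasibility cutoff (score units).  cell_size: grid
    edge in projection units; None triggers the automatic heuristic (span
    of the start plus 100 random perturbations, divided by 10).  p_exterior:
    bias toward frontier cells.  goal/goal_bias/goal_tolerance configure
    directed search; the stopping metric is mean wrapped torsion distance
    (degrees).  budget counts iterations (move attempts).
    """

    energy_threshold: float = 5.0
    cell_size: float | None = None
    p_exterior: float = 0.75
    goal: Conformation | None = None
    goal_bias: float = 0.05
    goal_tolerance: float = 5.0
    budget: int = 10_000
    seed: int = 0
    max_delta: float = 10.0
    closure: ClosureConfig = field(default_factory=ClosureConfig)
    min_iters: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.p_exterior <= 1 or not 0 <= self.goal_bias <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.budget < 0:
            raise ValueError("budget must be >= 0")


def _auto_cell_size(start, M, rng, max_delta):
    """Span of the start plus 100 random perturbations, divided by 10."""
    pts = [project(M, start.dihedrals)]
    for _ in range(100):
        res = dihedral_perturbation(
            start, range(1, start.n_residues + 1), max_delta, rng
        )
        pts.append(project(M, res.conformation.dihedrals))
    pts = np.asarray(pts)
    span = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
    return max(span / 10.0, 1e-6)


def _loop_runs(subset, n_res: int) -> list[tuple[int, int]]:
    """Contiguous runs of a subset clipped to the closable range
    (residue 2 .. n-1), keeping those with >= 3 residues."""
    runs = []
    for lo, hi in contiguous_runs(subset.residues):
        lo, hi = max(lo, 2), min(hi, n_res - 1)
        if hi - lo + 1 >= 3:
            runs.append((lo, hi))
    return runs


def _apply_schema_move(conf, subset, kind, energy_fn, config, rng):
    params = subset.params
    if kind == "dihedral":
        return dihedral_perturbation(
            conf, subset.residues, params.get("max_delta", config.max_delta), rng
        )
    if kind == "loop":
        runs = _loop_runs(subset, conf.n_residues)
        if not runs:
            from .moves import MoveResult
            return MoveResult(conf, "loop", success=False,
                              diagnostics={"reason": "no closable run in subset"})
        return loop_sample(conf, runs, rng, config.closure)
    if kind == "rigid":
        runs = _loop_runs(subset, conf.n_residues)
        if not runs:
            from .moves import MoveResult
            return MoveResult(conf, "rigid", success=False,
                              diagnostics={"reason": "no closable run in subset"})
        run = runs[int(rng.integers(len(runs)))]
        return rigid_body_move(
            conf, run,
            params.get("max_disp", 1.0), params.get("max_rot", 5.0),
            rng, config.closure,
        )
    if kind == "minimize":
        return minimization_move(conf, energy_fn, max_iters=config.min_iters)
    raise ValueError(f"unknown move kind {kind!r}")


def _goal_step(conf, goal, max_delta):
    """Step every defined torsion toward the goal along the shortest arc,
    at most max_delta degrees each."""
    dih = conf.dihedrals.copy()
    diff = wrap_angle(np.where(np.isfinite(goal.dihedrals - dih),
                               goal.dihedrals - dih, 0.0))
    step = np.clip(diff, -max_delta, max_delta)
    mask = np.isfinite(dih)
    dih[mask] = wrap_angle(dih[mask] + step[mask])
    return build_backbone(conf.sequence, dih)


def explore(
    start: Conformation,
    schema: Schema,
    energy_fn,
    config: PlannerConfig,
) -> ExplorationTree:
    """Grow the exploration tree from ``start``.

    Runs the select-cell / select-node / move / accept loop until the
    iteration budget is exhausted or, in directed mode, a node within
    ``goal_tolerance`` (mean wrapped torsion distance, degrees) of the goal
    exists.  Every accepted node satisfies energy <= threshold; full
    provenance (parent, generating move) is recorded.  Fully deterministic
    for a fixed (start, schema, config, seed).
    """
    rng = np.random.default_rng(config.seed)
    # canonical frame: rebuild from torsions so coordinates and dihedrals
    # are exactly kinematically consistent regardless of the input frame
    start = build_backbone(start.sequence, extract_dihedrals(start))
    if not is_feasible(start, energy_fn, config.energy_threshold):
        raise ValueError(
            f"infeasible start: energy {start.energy:g} exceeds threshold "
            f"{config.energy_threshold:g}"
        )
    M = make_projection(n_defined(start.dihedrals), int(rng.integers(2**31)))
    cell_size = config.cell_size
    if cell_size is None:
        cell_size = _auto_cell_size(start, M, np.random.default_rng(
            int(rng.integers(2**31))), config.max_delta)
    grid = DensityGrid(cell_size)

    goal = config.goal
    if goal is not None and goal.sequence != start.sequence:
        raise ValueError("start and goal must share a sequence")

    def goal_dist(conf) -> float:
        return dihedral_distance(conf.dihedrals, goal.dihedrals)

    p0 = project(M, start.dihedrals)
    root = TreeNode(0, None, start, None, None, start.energy, p0,
                    grid.insert(0, p0))
    tree = ExplorationTree([root], grid, M)
    if goal is not None and goal_dist(start) <= config.goal_tolerance:
        tree.goal_reached = 0
        return tree

    for it in range(config.budget):
        tree.iterations = it + 1
        cell = select_cell(grid, rng, config.p_exterior)
        node = tree.nodes[int(rng.choice(grid.cells[cell]))]
        if goal is not None and rng.random() < config.goal_bias:
            cand = _goal_step(node.conformation, goal, config.max_delta)
            subset_id, kind = None, "goal_step"
            ok = True
        else:
            subset_id, kind = sample_move(schema, rng)
            res = _apply_schema_move(
                node.conformation, schema.subset(subset_id), kind,
                energy_fn, config, rng,
            )
            cand, ok = res.conformation, res.success
        if not ok:
            continue
        if not is_feasible(cand, energy_fn, config.energy_threshold):
            continue
        nid = len(tree.nodes)
        pt = project(M, cand.dihedrals)
        new = TreeNode(nid, node.id, cand, subset_id, kind, cand.energy,
                       pt, grid.insert(nid, pt))
        tree.nodes.append(new)
        if goal is not None and goal_dist(cand) <= config.goal_tolerance:
            tree.goal_reached = nid
            break
    return tree


def extract_path(tree: ExplorationTree, node_id: int) -> list[Conformation]:
    """Root-to-node conformation sequence via parent links."""
    if not 0 <= node_id < len(tree.nodes):
        raise KeyError(f"unknown node id {node_id}")
    path = []
    cur: int | None = node_id
    while cur is not None:
        node = tree.nodes[cur]
        path.append(node.conformation)
        cur = node.parent
    return path[::-1]
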