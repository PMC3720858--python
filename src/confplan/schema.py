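"""Residue-subset schemas: which part of the chain moves, and how.

A schema is a weighted collection of residue subsets; each subset carries
its own probability distribution over move kinds and optional per-move
parameter overrides.  Subsets may overlap and need not be contiguous.  A
default schema can be generated automatically from a per-residue secondary
structure annotation (H helix, E sheet, L loop): one subset per secondary
structure element, weighted so that loops are sampled far more often than
sheets or helices, plus a whole-protein subset that hosts the rare global
moves (including energy minimization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .moves import MOVE_KINDS

__all__ = [
    "ResidueSubset",
    "Schema",
    "auto_schema",
    "sample_move",
    "load_schema",
    "save_schema",
    "validate_schema",
    "parse_residue_ranges",
    "contiguous_runs",
    "ALL_RESIDUES_ID",
]

ALL_RESIDUES_ID = "all"

# automatic schema constants: element sampling weights by secondary
# structure class, probability of the whole-protein subset, and its internal
# move distribution (chosen so the unconditional minimization rate is
# exactly 0.09 * 1/9 = 1%)
AUTO_WEIGHTS = {"L": 1.0, "E": 0.2, "H": 0.1}
ALL_RESIDUES_PROB = 0.09
DEFAULT_ELEMENT_MOVES = {"dihedral": 1 / 3, "loop": 1 / 3, "rigid": 1 / 3}
ALL_RESIDUES_MOVES = {"minimize": 1 / 9, "dihedral": 8 / 27,
                      "loop": 8 / 27, "rigid": 8 / 27}


@dataclass
class ResidueSubset:
    """A named set of residue indices (1-based, possibly non-contiguous)
    with a selection weight and a move-kind distribution."""

    id: str
    residues: frozenset[int]
    weight: float
    moves: dict[str, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = frozenset(int(r) for r in self.residues)
        if not self.residues:
            raise ValueError(f"subset {self.id!r}: residue set is empty")
        if self.weight < 0:
            raise ValueError(f"subset {self.id!r}: weight must be >= 0")
        total = sum(self.moves.values())
        if total <= 0:
            raise ValueError(f"subset {self.id!r}: move distribution is empty")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"subset {self.id!r}: move probabilities sum to {total:g}; renormalizing"
            )
            self.moves = {k: v / total for k, v in self.moves.items()}
        unknown = set(self.moves) - set(MOVE_KINDS)
        if unknown:
            raise ValueError(f"subset {self.id!r}: unknown move kinds {sorted(unknown)}")


@dataclass
class Schema:
    """List of subsets plus their normalized selection probabilities."""

    subsets: list[ResidueSubset]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.subsets),):
            raise ValueError("one probability per subset required")
        if (p < 0).any() or p.sum() <= 0:
            raise ValueError("probabilities must be nonnegative with positive sum")
        if abs(p.sum() - 1.0) > 1e-9:
            warnings.warn(
                f"subset probabilities sum to {p.sum():g}; renormalizing"
            )
        self.probabilities = p / p.sum()

    def subset(self, subset_id: str) -> ResidueSubset:
        for s in self.subsets:
            if s.id == subset_id:
                return s
        raise KeyError(subset_id)


def ss_elements(ss: str) -> list[tuple[str, int, int]]:
    """Maximal same-label runs of a secondary structure string as
    (label, first_residue, last_residue), 1-based inclusive."""
    runs = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            runs.append((ss[start], start + 1, i))
            start = i
    return runs


def auto_schema(ss: str) -> Schema:
    """Automatic schema from a secondary structure annotation.

    One subset per secondary structure element, weighted 1.0 (loop),
    0.2 (sheet), 0.1 (helix); the whole-protein subset is selected with
    fixed probability 0.09 and the remaining 0.91 is split over the
    elements proportionally to weight.  Element subsets draw the three
    perturbation moves with equal probability; the whole-protein subset's
    internal distribution puts 1/9 on minimization so that minimization
    runs 1% of the time overall.
    """
    if not ss:
        raise ValueError("empty secondary structure annotation")
    bad = set(ss) - set("HEL")
    if bad:
        raise ValueError(f"unknown secondary structure labels: {sorted(bad)}")
    subsets = []
    weights = []
    for k, (label, lo, hi) in enumerate(ss_elements(ss)):
        subsets.append(
            ResidueSubset(
                id=f"{label}{k + 1}_{lo}-{hi}",
                residues=frozenset(range(lo, hi + 1)),
                weight=AUTO_WEIGHTS[label],
                moves=dict(DEFAULT_ELEMENT_MOVES),
            )
        )
        weights.append(AUTO_WEIGHTS[label])
    weights = np.asarray(weights, dtype=float)
    probs = (1.0 - ALL_RESIDUES_PROB) * weights / weights.sum()
    subsets.append(
        ResidueSubset(
            id=ALL_RESIDUES_ID,
            residues=frozenset(range(1, len(ss) + 1)),
            weight=ALL_RESIDUES_PROB,
            moves=dict(ALL_RESIDUES_MOVES),
        )
    )
    return Schema(subsets, np.append(probs, ALL_RESIDUES_PROB))


def sample_move(schema: Schema, rng: np.random.Generator) -> tuple[str, str]:
    """Draw a (subset id, move kind) pair: subset by selection probability,
    then move kind from that subset's distribution."""
    i = int(rng.choice(len(schema.subsets), p=schema.probabilities))
    s = schema.subsets[i]
    kinds = sorted(s.moves)
    p = np.array([s.moves[k] for k in kinds])
    kind = kinds[int(rng.choice(len(kinds), p=p / p.sum()))]
    return s.id, kind


def parse_residue_ranges(ranges) -> frozenset[int]:
    """Parse "45-55,87-91" (1-based inclusive) or an explicit int list."""
    if isinstance(ranges, (list, tuple, set, frozenset)):
        return frozenset(int(r) for r in ranges)
    out: set[int] = set()
    for part in str(ranges).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-")
            lo, hi = int(lo), int(hi)
            if hi < lo:
                raise ValueError(f"range {part!r}: end before start")
            out.update(range(lo, hi + 1))
        else:
            out.add(int(part))
    return frozenset(out)


def format_residue_ranges(residues) -> str:
    parts = []
    for lo, hi in contiguous_runs(residues):
        parts.append(str(lo) if lo == hi else f"{lo}-{hi}")
    return ",".join(parts)


def contiguous_runs(residues) -> list[tuple[int, int]]:
    """Split a residue index set into maximal contiguous (lo, hi) runs."""
    rs = sorted(set(int(r) for r in residues))
    if not rs:
        return []
    runs = []
    lo = prev = rs[0]
    for r in rs[1:]:
        if r == prev + 1:
            prev = r
        else:
            runs.append((lo, prev))
            lo = prev = r
    runs.append((lo, prev))
    return runs


def load_schema(path) -> Schema:
    """Load an expert schema from a YAML/JSON config.

    Format: a list (optionally under a ``subsets`` key) of
    ``{id, residues: "45-55,87-91", probability|weight, moves: {kind: prob},
    params: {...}}``.  Selection probabilities not summing to one are
    renormalized with a warning.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"{path}: malformed schema config: {exc}") from exc
    if isinstance(doc, dict):
        doc = doc.get("subsets", doc)
    if not isinstance(doc, list) or not doc:
        raise ValueError(f"{path}: expected a non-empty list of subsets")
    subsets, probs = [], []
    for k, entry in enumerate(doc):
        if not isinstance(entry, dict) or "residues" not in entry:
            raise ValueError(f"{path}: subset #{k + 1} lacks a 'residues' field")
        p = entry.get("probability", entry.get("weight"))
        if p is None:
            raise ValueError(
                f"{path}: subset #{k + 1} needs a 'probability' or 'weight'"
            )
        subsets.append(
            ResidueSubset(
                id=str(entry.get("id", f"subset{k + 1}")),
                residues=parse_residue_ranges(entry["residues"]),
                weight=float(p),
                moves=dict(entry.get("moves", DEFAULT_ELEMENT_MOVES)),
                params=dict(entry.get("params", {})),
            )
        )
        probs.append(float(p))
    # Schema renormalizes (warning if the listed values do not sum to 1)
    return Schema(subsets, np.asarray(probs))


def save_schema(schema: Schema, path) -> None:
    doc = {
        "subsets": [
            {
                "id": s.id,
                "residues": format_residue_ranges(s.residues),
                "probability": float(p),
                "moves": {k: float(v) for k, v in s.moves.items()},
                **({"params": s.params} if s.params else {}),
            }
            for s, p in zip(schema.subsets, schema.probabilities)
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def validate_schema(schema: Schema, residue_count: int) -> list[str]:
    """Check subsets against the chain length; returns diagnostics (empty
    when valid) and raises on out-of-range residues."""
    diagnostics = []
    for s in schema.subsets:
        out = [r for r in s.residues if not 1 <= r <= residue_count]
        if out:
            raise ValueError(
                f"subset {s.id!r} references residues {sorted(out)} outside "
                f"1..{residue_count}"
            )
        total = sum(s.moves.values())
        if abs(total - 1.0) > 1e-9:
            diagnostics.append(f"subset {s.id!r}: move probabilities sum to {total:g}")
    total_p = float(np.sum(schema.probabilities))
    if abs(total_p - 1.0) > 1e-9:
        diagnostics.append(f"subset probabilities sum to {total_p:g}")
    return diagnostics
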