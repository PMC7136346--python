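"""Per-frame secondary-structure fractions and CD-guided frame selection.

An MD trajectory is represented here only by its per-frame per-residue
secondary-structure assignment strings (DSSP-style one-character codes, as
produced by DSSP or CPPTRAJ).  Codes are consolidated into four categories
(helix, strand, turn, unordered) and counted per frame, giving each frame a
fraction vector S_i.  Frames are then extracted *in pairs*: a pair (i, j)
is accepted when the pair-averaged fraction matches the CD-deconvolution
target S₀ within a per-category tolerance φ,

    |(S_i^k + S_j^k)/2 − S₀^k| < φ   for every category k,

with φ = 0.035 by default.  The refined ensemble is the union of frames
appearing in at least one accepted pair; both the pair count and the
unique-frame count are reported.

Two selection strategies are provided and return identical pair sets: a
brute-force scan over all N(N−1)/2 pairs, and a sort-based strategy that
sorts frames by helix fraction and restricts the partner search to the
interval where the helix inequality can hold (the default above 20,000
frames, where the full scan's quadratic cost bites).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deconv import FourFractions
from .errors import ContractError, MappingError, ValidationError
from .refbasis import FOUR_CATEGORIES

#: Default assignment-code consolidation (DSSP codes and the CPPTRAJ
#: variants): α- and 3-10 helix → helix; parallel/antiparallel sheet and
#: isolated codes 'E'/'B'(sheet) → strand; turn and bend → turn; π-helix,
#: isolated β-bridge and "none" → unordered.  Unassigned residues
#: (termini, chain breaks: ' ', '-', '.', '0') count as unordered.
DEFAULT_CODE_TABLE: dict[str, str] = {
    "H": "helix",        # α-helix
    "G": "helix",        # 3-10 helix
    "E": "strand",       # β-sheet (parallel or extended)
    "A": "strand",       # antiparallel β-sheet (CPPTRAJ)
    "P": "strand",       # parallel β-sheet (CPPTRAJ)
    "T": "turn",         # turn
    "S": "turn",         # bend
    "I": "unordered",    # π-helix (demoted: not a stable category)
    "B": "unordered",    # isolated β-bridge
    "C": "unordered",    # coil / none
    "0": "unordered",
    " ": "unordered",
    "-": "unordered",
    ".": "unordered",
}

#: Pair-selection tolerance per category from the CD-guided refinement.
DEFAULT_PHI = 0.035

#: Frame count above which select_frame_pairs defaults to sorted_window.
SORTED_WINDOW_THRESHOLD = 20_000


@dataclass(frozen=True)
class AssignmentTrajectory:
    """Per-frame per-residue secondary-structure code strings."""

    frames: tuple[str, ...]
    n_residues: int
    code_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CODE_TABLE))

    def __post_init__(self):
        frames = tuple(self.frames)
        if not frames:
            raise ValidationError("trajectory has no frames")
        for i, f in enumerate(frames):
            if len(f) != self.n_residues:
                raise ValidationError(
                    f"frame {i} has {len(f)} residues, expected {self.n_residues}"
                )
        bad = set(self.code_table.values()) - set(FOUR_CATEGORIES)
        if bad:
            raise ValidationError(f"code table maps to unknown categories {bad}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)


class FrameFractionTable:
    """Per-frame four-category fraction vectors (rows sum to 1)."""

    def __init__(self, fractions: np.ndarray):
        arr = np.asarray(fractions, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValidationError(f"expected (n_frames, 4) array, got {arr.shape}")
        if np.any(arr < 0) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("rows must be non-negative and sum to 1")
        self.fractions = arr

    def __len__(self) -> int:
        return self.fractions.shape[0]

    def frame(self, i: int) -> FourFractions:
        return FourFractions.from_array(self.fractions[i])

    def mean(self) -> FourFractions:
        return FourFractions.from_array(self.fractions.mean(axis=0))


@dataclass(frozen=True)
class SelectionCriteria:
    """CD-derived target fractions S₀ and the per-category tolerance φ."""

    target: FourFractions
    phi: float = DEFAULT_PHI

    def __post_init__(self):
        if self.phi < 0:
            raise ValidationError(f"phi must be >= 0, got {self.phi}")


@dataclass(frozen=True)
class SelectionResult:
    """Accepted frame pairs and the unique-frame union they span."""

    pairs: tuple[tuple[int, int], ...]
    frames: tuple[int, ...]
    n_pairs: int
    n_frames: int

    @classmethod
    def from_pairs(cls, pairs) -> "SelectionResult":
        pairs = tuple(sorted((int(i), int(j)) for i, j in pairs))
        for i, j in pairs:
            if not i < j:
                raise ValidationError(f"pair ({i}, {j}) violates i < j")
        frames = tuple(sorted({k for p in pairs for k in p}))
        return cls(pairs=pairs, frames=frames, n_pairs=len(pairs), n_frames=len(frames))

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "frames": list(self.frames),
            "n_pairs": self.n_pairs,
            "n_frames": self.n_frames,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        doc = json.loads(Path(path).read_text())
        return cls.from_pairs(doc["pairs"])


def fractions_per_frame(traj: AssignmentTrajectory) -> FrameFractionTable:
    """Consolidated category counts per frame, divided by the residue count."""
    cat_index = {}
    for code, cat in traj.code_table.items():
        cat_index[code] = FOUR_CATEGORIES.index(cat)
    out = np.zeros((len(traj), 4))
    for fi, frame in enumerate(traj.frames):
        for ch in frame:
            try:
                out[fi, cat_index[ch]] += 1
            except KeyError:
                raise MappingError(
                    f"unknown assignment code {ch!r} in frame {fi}"
                ) from None
    return FrameFractionTable(out / traj.n_residues)


def _pairs_exhaustive(S: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> list[tuple[int, int]]:
    # Accept (i, j) iff lo_k < S_i^k + S_j^k < hi_k for all k, where
    # lo = 2(S0 - phi), hi = 2(S0 + phi).  Chunked over i to bound memory.
    n = S.shape[0]
    pairs: list[tuple[int, int]] = []
    chunk = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        sums = S[start:stop, None, :] + S[None, :, :]      # (c, n, 4)
        ok = np.all((sums > lo) & (sums < hi), axis=2)
        ii, jj = np.nonzero(ok)
        for a, b in zip(ii + start, jj):
            if a < b:
                pairs.append((int(a), int(b)))
    return pairs


def _pairs_sorted_window(S: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> list[tuple[int, int]]:
    # Sort by helix fraction; for each frame the helix inequality confines
    # partners to a contiguous index window, inside which all four
    # categories are checked exactly.
    n = S.shape[0]
    order = np.argsort(S[:, 0], kind="stable")
    h = S[order, 0]
    pairs: list[tuple[int, int]] = []
    for a in range(n):
        lo_h, hi_h = lo[0] - h[a], hi[0] - h[a]
        b0 = int(np.searchsorted(h, lo_h, side="right"))
        b1 = int(np.searchsorted(h, hi_h, side="left"))
        b0 = max(b0, a + 1)
        if b0 >= b1:
            continue
        cand = order[b0:b1]
        sums = S[order[a]] + S[cand]
        ok = np.all((sums > lo) & (sums < hi), axis=1)
        ia = int(order[a])
        for ib in cand[ok]:
            i, j = (ia, int(ib)) if ia < ib else (int(ib), ia)
            pairs.append((i, j))
    return pairs


def select_frame_pairs(
    table: FrameFractionTable,
    criteria: SelectionCriteria,
    strategy: str = "auto",
) -> SelectionResult:
    """Select frame pairs whose averaged fractions match the CD target.

    A pair (i, j), i < j, is accepted iff |(S_i^k + S_j^k)/2 − S₀^k| < φ
    holds simultaneously for all four categories (strict inequality; φ = 0
    keeps only pairs matching the target exactly).  ``strategy`` is
    ``exhaustive``, ``sorted_window`` or ``auto`` (exhaustive below
    :data:`SORTED_WINDOW_THRESHOLD` frames); both strategies return the
    identical pair set.
    """
    if len(table) < 2:
        raise ContractError("pair selection needs at least 2 frames")
    if strategy == "auto":
        strategy = (
            "sorted_window" if len(table) > SORTED_WINDOW_THRESHOLD else "exhaustive"
        )
    S = table.fractions
    t = criteria.target.as_array()
    if criteria.phi == 0:
        # exact-match mode: the open interval degenerates to a point
        sums = S[:, None, :] + S[None, :, :]
        ok = np.all(sums == 2.0 * t, axis=2)
        ii, jj = np.nonzero(ok)
        pairs = [(int(a), int(b)) for a, b in zip(ii, jj) if a < b]
        return SelectionResult.from_pairs(pairs)
    lo = 2.0 * (t - criteria.phi)
    hi = 2.0 * (t + criteria.phi)
    if strategy == "exhaustive":
        pairs = _pairs_exhaustive(S, lo, hi)
    elif strategy == "sorted_window":
        pairs = _pairs_sorted_window(S, lo, hi)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return SelectionResult.from_pairs(pairs)


# ---------------------------------------------------------------------------
# Ensemble spread (all-pairs best-fit RMSD)
# ---------------------------------------------------------------------------

def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit (Kabsch) RMSD between two (n_atoms, 3) coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ContractError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = ac @ R.T - bc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def ensemble_spread(coords: np.ndarray) -> tuple[float, float]:
    """Max and standard deviation of all-pairs best-fit RMSD (Å).

    ``coords`` is an (n_models, n_atoms, 3) array (pass
    ``stack.coord`` for a biotite ``AtomArrayStack``).
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ContractError(
            f"need (n_models >= 2, n_atoms, 3) coordinates, got {coords.shape}"
        )
    n = coords.shape[0]
    vals = [
        superposed_rmsd(coords[i], coords[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.max(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# Assignment I/O
# ---------------------------------------------------------------------------

def load_assignments(
    path: str | Path, code_table: dict[str, str] | None = None
) -> AssignmentTrajectory:
    """Read one code string per line (frame order); '#' comments allowed."""
    lines = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            continue
        if raw.strip("\r"):
            lines.append(raw.rstrip("\r"))
    if not lines:
        raise ValidationError(f"{Path(path).name}: no assignment frames")
    return AssignmentTrajectory(
        frames=tuple(lines),
        n_residues=len(lines[0]),
        code_table=code_table or dict(DEFAULT_CODE_TABLE),
    )


def save_assignments(traj: AssignmentTrajectory, path: str | Path) -> None:
    Path(path).write_text("\n".join(traj.frames) + "\n")


__all__ = [
    "DEFAULT_CODE_TABLE",
    "DEFAULT_PHI",
    "AssignmentTrajectory",
    "FrameFractionTable",
    "SelectionCriteria",
    "SelectionResult",
    "fractions_per_frame",
    "select_frame_pairs",
    "superposed_rmsd",
    "ensemble_spread",
    "load_assignments",
    "save_assignments",
]
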