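"""Deconvolution quality statistics and the disorder-cutoff sweep.

Deconvolution accuracy is scored against proteins of known structure by the
root-mean-square deviation δ and the Pearson correlation r between the
CD-derived fractions f^CD and the structure-derived fractions f^x:

    δ = sqrt( Σᵢ (fᵢ^CD − fᵢ^x)² / N ),      r = Pearson(f^CD, f^x).

The index can run over proteins within one category (per-category
statistics, N = protein count) or over all protein × category pairs
(pooled statistics, N = 4 × protein count); both are reported.  The
disorder-cutoff sweep recomputes both on nested subsets of the benchmark,
keeping only proteins whose *known* unordered fraction is strictly above
each cutoff, to probe how accuracy depends on disorder content.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .deconv import FourFractions
from .errors import ContractError, UndefinedStatisticError
from .refbasis import FOUR_CATEGORIES

#: Valid category scopes for delta_rmsd / corr_coefficient.
SCOPES = FOUR_CATEGORIES + ("pooled",)


@dataclass(frozen=True)
class ValidationRecord:
    """One benchmark protein: CD-deconvolved vs known four-category fractions."""

    name: str
    deconvolved: FourFractions
    known: FourFractions


@dataclass(frozen=True)
class ValidationSummary:
    """Statistics for one disorder cutoff.

    ``delta`` and ``corr`` map each scope in :data:`SCOPES` to its value;
    ``defined`` is False when the subset is too small (< 2 proteins) or a
    correlation scope is constant, in which case the affected entries are
    ``None``.
    """

    cutoff: float
    n_proteins: int
    delta: dict[str, float | None]
    corr: dict[str, float | None]
    defined: bool


def _scope_arrays(
    records: list[ValidationRecord], scope: str
) -> tuple[np.ndarray, np.ndarray]:
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    cd = np.array([r.deconvolved.as_array() for r in records])
    kn = np.array([r.known.as_array() for r in records])
    if scope == "pooled":
        return cd.ravel(), kn.ravel()
    j = FOUR_CATEGORIES.index(scope)
    return cd[:, j], kn[:, j]


def delta_rmsd(records: list[ValidationRecord], scope: str = "pooled") -> float:
    """δ: root-mean-square deviation between deconvolved and known fractions.

    Per-category scopes average over proteins; ``pooled`` averages over all
    protein × category pairs.
    """
    if not records:
        raise ContractError("delta_rmsd needs at least one record")
    cd, kn = _scope_arrays(records, scope)
    return float(np.sqrt(np.mean((cd - kn) ** 2)))


def corr_coefficient(records: list[ValidationRecord], scope: str = "pooled") -> float:
    """Pearson correlation r between deconvolved and known fractions."""
    if len(records) < 2:
        raise ContractError("corr_coefficient needs at least two records")
    cd, kn = _scope_arrays(records, scope)
    if np.ptp(cd) == 0 or np.ptp(kn) == 0:
        raise UndefinedStatisticError(
            f"correlation undefined: constant input on scope {scope!r}"
        )
    return float(np.corrcoef(cd, kn)[0, 1])


def disorder_cutoff_sweep(
    records: list[ValidationRecord], cutoffs
) -> list[ValidationSummary]:
    """Recompute δ and r on subsets with known unordered fraction > cutoff.

    The comparison is strict ("above X% unordered"); cutoff 0 is special-
    cased to mean the full record set.  Subsets are nested, so n_proteins
    is non-increasing in the cutoff.  Subsets with fewer than two proteins
    yield a summary flagged ``defined=False`` instead of raising.
    """
    summaries = []
    for cutoff in cutoffs:
        cutoff = float(cutoff)
        if not (0 <= cutoff < 1):
            raise ContractError(f"cutoff {cutoff} outside [0, 1)")
        if cutoff == 0:
            subset = list(records)
        else:
            subset = [r for r in records if r.known.unordered > cutoff]
        delta: dict[str, float | None] = {}
        corr: dict[str, float | None] = {}
        defined = len(subset) >= 2
        for scope in SCOPES:
            delta[scope] = delta_rmsd(subset, scope) if subset else None
            if defined:
                try:
                    corr[scope] = corr_coefficient(subset, scope)
                except UndefinedStatisticError:
                    corr[scope] = None
                    defined = False
            else:
                corr[scope] = None
        summaries.append(
            ValidationSummary(
                cutoff=cutoff,
                n_proteins=len(subset),
                delta=delta,
                corr=corr,
                defined=defined,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Record-file interface (CSV), the representation of external benchmarks.
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "name",
    "helix_cd", "strand_cd", "turn_cd", "unord_cd",
    "helix_known", "strand_known", "turn_known", "unord_known",
]


def load_records(path: str | Path) -> list[ValidationRecord]:
    """Read validation records from CSV (columns: name, *_cd, *_known)."""
    records = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ContractError(f"records CSV missing columns {sorted(missing)}")
        for row in reader:
            records.append(
                ValidationRecord(
                    name=row["name"],
                    deconvolved=FourFractions(
                        float(row["helix_cd"]), float(row["strand_cd"]),
                        float(row["turn_cd"]), float(row["unord_cd"]),
                    ),
                    known=FourFractions(
                        float(row["helix_known"]), float(row["strand_known"]),
                        float(row["turn_known"]), float(row["unord_known"]),
                    ),
                )
            )
    return records


def save_records(records: list[ValidationRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.name, *r.deconvolved.as_array(), *r.known.as_array()]
            )


def save_summaries(summaries: list[ValidationSummary], path: str | Path) -> None:
    """Write sweep summaries as CSV (one row per cutoff × scope)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cutoff", "n_proteins", "scope", "delta", "corr", "defined"])
        for s in summaries:
            for scope in SCOPES:
                writer.writerow(
                    [s.cutoff, s.n_proteins, scope,
                     "" if s.delta[scope] is None else s.delta[scope],
                     "" if s.corr[scope] is None else s.corr[scope],
                     s.defined]
                )


__all__ = [
    "SCOPES",
    "ValidationRecord",
    "ValidationSummary",
    "delta_rmsd",
    "corr_coefficient",
    "disorder_cutoff_sweep",
    "load_records",
    "save_records",
    "save_summaries",
]
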