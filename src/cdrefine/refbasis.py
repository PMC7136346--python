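"""Reference basis sets and CD spectra: data model, I/O, grid alignment.

A circular-dichroism (CD) spectrum is a curve of molar CD (Δε, M⁻¹cm⁻¹)
against wavelength (nm).  A reference basis set pairs one CD spectrum per
reference protein with that protein's six-category secondary-structure
fractions (helix regular/distorted, strand regular/distorted, turn,
unordered), the layout used by the CDPro ecosystem's SDP48-style sets.
Deconvolution expresses a measured spectrum as a non-negative combination
of the basis spectra; everything downstream needs the measured spectrum and
the basis to share one wavelength grid, which :func:`regrid` and
:func:`restrict_overlap` arrange.

Native serialization is JSON/CSV with a documented schema; a reader for
CDPro-style fixed-format files is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParseError, RangeError, ValidationError

#: Six-category secondary-structure labels, in matrix row order.
SIX_CATEGORIES: tuple[str, ...] = (
    "helix_regular",
    "helix_distorted",
    "strand_regular",
    "strand_distorted",
    "turn",
    "unordered",
)

#: Consolidated four-category labels.
FOUR_CATEGORIES: tuple[str, ...] = ("helix", "strand", "turn", "unordered")

#: Column-sum tolerance for fraction vectors in strict mode.
FRACTION_SUM_TOL = 0.02

#: Mean-residue ellipticity (deg cm² dmol⁻¹) to Δε (M⁻¹cm⁻¹).
MRE_TO_DELTA_EPS = 1.0 / 3298.0


def mre_to_delta_eps(theta):
    """Convert mean-residue ellipticity [θ] (deg cm² dmol⁻¹) to Δε.

    Δε = [θ] / 3298.
    """
    return np.asarray(theta, dtype=float) * MRE_TO_DELTA_EPS


def _check_wavelengths(wl: np.ndarray) -> None:
    if wl.ndim != 1 or wl.size < 2:
        raise ValidationError(f"need >= 2 wavelengths, got shape {wl.shape}")
    dw = np.diff(wl)
    if np.any(dw == 0):
        dup = wl[:-1][dw == 0]
        raise ValidationError(f"duplicate wavelengths: {dup.tolist()}")
    if np.any(dw < 0):
        raise ValidationError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class CDSpectrum:
    """One CD spectrum on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing wavelengths in nm.  Uniform spacing is not
        required.
    values : array of float
        Δε at each wavelength, in M⁻¹cm⁻¹.
    label : str
        Free-text identifier.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape:
            raise ValidationError(
                f"wavelengths ({wl.shape}) and values ({vals.shape}) differ in length"
            )
        _check_wavelengths(wl)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


@dataclass(frozen=True)
class ReferenceSet:
    """A CD reference basis: spectra matrix C and fraction matrix A.

    ``spectra`` has one row per wavelength and one column per reference
    protein (the C matrix); ``fractions`` is 6 × n_proteins (the A matrix),
    rows ordered as :data:`SIX_CATEGORIES`.  Fraction columns must be
    non-negative and sum to 1 within :data:`FRACTION_SUM_TOL`.
    """

    wavelengths: np.ndarray
    spectra: np.ndarray
    fractions: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        C = np.asarray(self.spectra, dtype=float)
        A = np.asarray(self.fractions, dtype=float)
        _check_wavelengths(wl)
        if C.ndim != 2 or C.shape[0] != wl.size:
            raise ValidationError(
                f"spectra shape {C.shape} incompatible with {wl.size} wavelengths"
            )
        n = C.shape[1]
        if n < 1:
            raise ValidationError("reference set needs >= 1 protein")
        names = tuple(self.names) if self.names else tuple(
            f"ref{i + 1:02d}" for i in range(n)
        )
        if len(names) != n:
            raise ValidationError(
                f"{len(names)} names for {n} spectra columns"
            )
        if A.shape != (len(SIX_CATEGORIES), n):
            raise ValidationError(
                f"fractions shape {A.shape}, expected (6, {n})"
            )
        if np.any(A < 0):
            bad = names[int(np.argwhere(np.any(A < 0, axis=0))[0, 0])]
            raise ValidationError(f"negative fraction entry for protein {bad!r}")
        sums = A.sum(axis=0)
        off = np.abs(sums - 1.0) > FRACTION_SUM_TOL
        if np.any(off):
            i = int(np.argmax(off))
            raise ValidationError(
                f"fraction column for protein {names[i]!r} sums to "
                f"{sums[i]:.4f} (must be 1 +/- {FRACTION_SUM_TOL})"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spectra", C)
        object.__setattr__(self, "fractions", A)
        object.__setattr__(self, "names", names)

    @property
    def n_proteins(self) -> int:
        return self.spectra.shape[1]

    def column(self, k: int) -> CDSpectrum:
        """Spectrum of reference protein ``k`` as a :class:`CDSpectrum`."""
        return CDSpectrum(self.wavelengths, self.spectra[:, k], label=self.names[k])


def _renormalized(fractions: np.ndarray) -> np.ndarray:
    sums = fractions.sum(axis=0)
    if np.any(sums <= 0):
        raise ValidationError("cannot renormalize a zero fraction column")
    return fractions / sums


def _build_refset(wavelengths, spectra, fractions, names, strict: bool) -> ReferenceSet:
    fractions = np.asarray(fractions, dtype=float)
    if not strict:
        if np.any(fractions < 0):
            raise ValidationError("negative fraction entry")
        fractions = _renormalized(fractions)
    return ReferenceSet(wavelengths, spectra, fractions, tuple(names))


# ---------------------------------------------------------------------------
# Spectrum I/O: two-column text, '#' comments, comma or whitespace delimited.
# ---------------------------------------------------------------------------

def load_spectrum(path: str | Path, label: str | None = None) -> CDSpectrum:
    """Read a two-column (wavelength nm, Δε) text file.

    Lines starting with ``#`` (or blank) are skipped; columns may be
    separated by whitespace or commas.  Rows are returned sorted by
    ascending wavelength.
    """
    path = Path(path)
    wl, vals = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            wl.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"{path.name}:{lineno}: non-numeric row {line!r}") from None
    if len(wl) < 2:
        raise ValidationError(f"{path.name}: need >= 2 data points, got {len(wl)}")
    order = np.argsort(wl)
    return CDSpectrum(
        np.asarray(wl)[order], np.asarray(vals)[order],
        label=label if label is not None else path.stem,
    )


def save_spectrum(spectrum: CDSpectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with a comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {spectrum.label}\n# wavelength_nm delta_eps\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.6g} {v:.12g}\n")


# ---------------------------------------------------------------------------
# ReferenceSet I/O (json, csv, cdpro dialects)
# ---------------------------------------------------------------------------

def load_reference_set(
    path: str | Path, dialect: str = "json", strict: bool = True
) -> ReferenceSet:
    """Load a reference basis set.

    Dialects
    --------
    ``json``
        ``{"wavelengths": [...], "proteins": [{"name": ..., "spectrum":
        [...], "fractions": [6 values]}, ...]}``.
    ``csv``
        A labelled matrix: header ``row,<name1>,<name2>,...``; six rows
        labelled by the :data:`SIX_CATEGORIES` names holding the fraction
        matrix, then one row per wavelength (label = wavelength in nm)
        holding the spectra matrix.
    ``cdpro``
        Fixed-format legacy layout: a first line ``n_proteins
        n_wavelengths``, then one line per wavelength (wavelength followed
        by n_proteins Δε values), then six lines of fractions in
        :data:`SIX_CATEGORIES` order (n_proteins values each), then
        optionally one line of protein names.

    ``strict=True`` rejects fraction columns whose sum deviates from 1 by
    more than 0.02; ``strict=False`` renormalizes them instead.
    """
    path = Path(path)
    if dialect == "json":
        return _load_refset_json(path, strict)
    if dialect == "csv":
        return _load_refset_csv(path, strict)
    if dialect == "cdpro":
        return _load_refset_cdpro(path, strict)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_refset_json(path: Path, strict: bool) -> ReferenceSet:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path.name}: invalid JSON at line {exc.lineno}") from None
    try:
        wl = np.asarray(doc["wavelengths"], dtype=float)
        proteins = doc["proteins"]
        names = [p["name"] for p in proteins]
        C = np.column_stack([np.asarray(p["spectrum"], dtype=float) for p in proteins])
        A = np.column_stack([np.asarray(p["fractions"], dtype=float) for p in proteins])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path.name}: malformed reference-set JSON ({exc})") from None
    return _build_refset(wl, C, A, names, strict)


def _load_refset_csv(path: Path, strict: bool) -> ReferenceSet:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path.name}:1: empty file")
    header = [c.strip() for c in lines[0].split(",")]
    if header[0] != "row":
        raise ParseError(f"{path.name}:1: header must start with 'row'")
    names = header[1:]
    frac_rows: dict[str, list[float]] = {}
    wl, spec_rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != len(header):
            raise ParseError(f"{path.name}:{lineno}: expected {len(header)} cells")
        label, vals = cells[0], cells[1:]
        try:
            row = [float(v) for v in vals]
        except ValueError:
            raise ParseError(f"{path.name}:{lineno}: non-numeric cell") from None
        if label in SIX_CATEGORIES:
            frac_rows[label] = row
        else:
            try:
                wl.append(float(label))
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: unknown row label {label!r}"
                ) from None
            spec_rows.append(row)
    missing = [c for c in SIX_CATEGORIES if c not in frac_rows]
    if missing:
        raise ParseError(f"{path.name}: missing fraction rows {missing}")
    order = np.argsort(wl)
    C = np.asarray(spec_rows)[order]
    A = np.asarray([frac_rows[c] for c in SIX_CATEGORIES])
    return _build_refset(np.asarray(wl)[order], C, A, names, strict)


def _load_refset_cdpro(path: Path, strict: bool) -> ReferenceSet:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    try:
        n_prot, n_wl = (int(tok) for tok in lines[0].split())
    except (ValueError, IndexError):
        raise ParseError(f"{path.name}:1: expected 'n_proteins n_wavelengths'") from None
    expected = 1 + n_wl + 6
    if len(lines) < expected:
        raise ParseError(f"{path.name}: expected >= {expected} lines, got {len(lines)}")
    wl, spec_rows = [], []
    for lineno, line in enumerate(lines[1 : 1 + n_wl], start=2):
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError:
            raise ParseError(f"{path.name}:{lineno}: non-numeric token") from None
        if len(row) != n_prot + 1:
            raise ParseError(
                f"{path.name}:{lineno}: expected {n_prot + 1} values, got {len(row)}"
            )
        wl.append(row[0])
        spec_rows.append(row[1:])
    frac_rows = []
    for lineno, line in enumerate(lines[1 + n_wl : 1 + n_wl + 6], start=2 + n_wl):
        try:
            row = [float(tok) for tok in line.split()]
        except ValueError:
            raise ParseError(f"{path.name}:{lineno}: non-numeric token") from None
        if len(row) != n_prot:
            raise ParseError(
                f"{path.name}:{lineno}: expected {n_prot} fractions, got {len(row)}"
            )
        frac_rows.append(row)
    names: list[str]
    if len(lines) > 1 + n_wl + 6:
        names = lines[1 + n_wl + 6].split()
        if len(names) != n_prot:
            raise ParseError(f"{path.name}: names line has {len(names)} entries")
    else:
        names = [f"ref{i + 1:02d}" for i in range(n_prot)]
    order = np.argsort(wl)
    return _build_refset(
        np.asarray(wl)[order], np.asarray(spec_rows)[order],
        np.asarray(frac_rows), names, strict,
    )


def save_reference_set(refset: ReferenceSet, path: str | Path, dialect: str = "json") -> None:
    """Write a reference set in the given dialect (see :func:`load_reference_set`)."""
    path = Path(path)
    if dialect == "json":
        doc = {
            "wavelengths": refset.wavelengths.tolist(),
            "proteins": [
                {
                    "name": refset.names[k],
                    "spectrum": refset.spectra[:, k].tolist(),
                    "fractions": refset.fractions[:, k].tolist(),
                }
                for k in range(refset.n_proteins)
            ],
        }
        path.write_text(json.dumps(doc))
    elif dialect == "csv":
        with path.open("w") as fh:
            fh.write("row," + ",".join(refset.names) + "\n")
            for i, cat in enumerate(SIX_CATEGORIES):
                fh.write(cat + "," + ",".join(f"{v:.17g}" for v in refset.fractions[i]) + "\n")
            for i, w in enumerate(refset.wavelengths):
                fh.write(f"{w:.17g}," + ",".join(f"{v:.17g}" for v in refset.spectra[i]) + "\n")
    elif dialect == "cdpro":
        with path.open("w") as fh:
            fh.write(f"{refset.n_proteins} {len(refset.wavelengths)}\n")
            for i, w in enumerate(refset.wavelengths):
                fh.write(f"{w:.17g} " + " ".join(f"{v:.17g}" for v in refset.spectra[i]) + "\n")
            for i in range(len(SIX_CATEGORIES)):
                fh.write(" ".join(f"{v:.17g}" for v in refset.fractions[i]) + "\n")
            fh.write(" ".join(refset.names) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Grid alignment
# ---------------------------------------------------------------------------

def regrid(spectrum: CDSpectrum, grid) -> CDSpectrum:
    """Linearly interpolate a spectrum onto a target wavelength grid.

    The target grid must lie inside the spectrum's span; extrapolation is
    refused with a :class:`RangeError` naming the offending wavelengths.
    Grid points already present are reproduced exactly.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.span
    outside = grid[(grid < lo) | (grid > hi)]
    if outside.size:
        raise RangeError(
            f"target wavelengths {outside.tolist()} outside spectrum span "
            f"[{lo}, {hi}] nm"
        )
    values = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return CDSpectrum(grid, values, label=spectrum.label)


def restrict_overlap(
    spectrum: CDSpectrum,
    refset: ReferenceSet,
    window: tuple[float, float] | None = None,
) -> tuple[CDSpectrum, ReferenceSet]:
    """Restrict a spectrum and reference set to a common wavelength grid.

    The common grid is the subset of the *reference* grid that lies inside
    both the window (endpoints inclusive) and the spectrum's span; the
    spectrum is regridded onto it.  Raises :class:`RangeError` if the
    intersection is empty.
    """
    lo, hi = spectrum.span
    if window is None:
        wlo, whi = -np.inf, np.inf
    else:
        wlo, whi = float(window[0]), float(window[1])
    mask = (
        (refset.wavelengths >= max(lo, wlo)) & (refset.wavelengths <= min(hi, whi))
    )
    if not np.any(mask):
        raise RangeError(
            f"no overlap between spectrum span [{lo}, {hi}] nm, reference span "
            f"[{refset.wavelengths[0]}, {refset.wavelengths[-1]}] nm and window "
            f"[{wlo}, {whi}] nm"
        )
    if mask.sum() < 2:
        raise RangeError("overlap window contains fewer than 2 wavelengths")
    grid = refset.wavelengths[mask]
    sub = ReferenceSet(grid, refset.spectra[mask], refset.fractions, refset.names)
    return regrid(spectrum, grid), sub


def spectra_grids_match(a: CDSpectrum, b) -> bool:
    """True if two spectra (or a spectrum and a reference set) share a grid."""
    wb = b.wavelengths
    return a.wavelengths.shape == wb.shape and np.array_equal(a.wavelengths, wb)


__all__ = [
    "SIX_CATEGORIES",
    "FOUR_CATEGORIES",
    "CDSpectrum",
    "ReferenceSet",
    "mre_to_delta_eps",
    "load_spectrum",
    "save_spectrum",
    "load_reference_set",
    "save_reference_set",
    "regrid",
    "restrict_overlap",
    "spectra_grids_match",
]
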