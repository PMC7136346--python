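"""Non-negative least-squares (NN-LSQ) deconvolution of CD spectra.

Given a measured spectrum b (Δε over a wavelength grid) and a reference
basis with spectra matrix C and fraction matrix A, the deconvolution solves

    minimize  Δ² = ‖C·x − b‖²   subject to  x ≥ 0,

with the weights deliberately *unbounded above* so amplitude mismatch
between the measurement and the reference set is absorbed by the fit.  The
six-category secondary-structure estimate is then the weight-normalized
combination of the reference fraction columns,

    d = A·x / ‖x‖₁,

which is a convex combination of the columns of A and therefore sums to 1
(an L2 normalization is available behind ``norm="l2"`` for comparison; it
does not preserve the unit sum).  The six categories are consolidated to
four (helix, strand, turn, unordered) by summing the regular/distorted
helix pair and the regular/distorted strand pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import ContractError, DegenerateFitError, ValidationError
from .refbasis import (
    FOUR_CATEGORIES,
    CDSpectrum,
    ReferenceSet,
    restrict_overlap,
    spectra_grids_match,
)

#: Weights below this are considered an all-zero (degenerate) fit.
_ZERO_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class FourFractions:
    """Consolidated secondary-structure fractions (helix, strand, turn, unordered)."""

    helix: float
    strand: float
    turn: float
    unordered: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValidationError(f"negative fraction in {arr.tolist()}")
        if arr.sum() > 1 + 1e-6:
            raise ValidationError(f"fractions sum to {arr.sum():.8f} > 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.helix, self.strand, self.turn, self.unordered], float)

    @classmethod
    def unchecked(cls, arr) -> "FourFractions":
        """Bypass invariant checks (L2-normalized fractions can sum > 1)."""
        obj = object.__new__(cls)
        for name, v in zip(FOUR_CATEGORIES, np.asarray(arr, dtype=float)):
            object.__setattr__(obj, name, float(v))
        return obj

    @classmethod
    def from_array(cls, arr) -> "FourFractions":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise ValidationError(f"expected 4 fractions, got shape {arr.shape}")
        return cls(*(float(v) for v in arr))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FOUR_CATEGORIES, self.as_array().tolist()))


@dataclass(frozen=True)
class DeconvolutionResult:
    """Full output of one NN-LSQ deconvolution.

    Attributes
    ----------
    weights : array
        Non-negative coefficient per reference protein (dimensionless,
        unbounded above).
    residual_sq : float
        Squared fitting residual Δ² = ‖C·x − b‖², in (M⁻¹cm⁻¹)².
    fractions6 : array
        Six-category fractions d (sums to 1 under L1 normalization).
    fractions4 : FourFractions
        Consolidated helix/strand/turn/unordered fractions.
    reconstructed : CDSpectrum
        C·x on the fitting grid.
    rmsd_delta_eps : float
        RMS deviation between reconstructed and measured spectrum (M⁻¹cm⁻¹).
    degenerate : bool
        True when the input spectrum fit to all-zero weights.
    """

    weights: np.ndarray
    residual_sq: float
    fractions6: np.ndarray
    fractions4: FourFractions
    reconstructed: CDSpectrum
    rmsd_delta_eps: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "weights": np.asarray(self.weights).tolist(),
            "residual_sq": self.residual_sq,
            "fractions6": np.asarray(self.fractions6).tolist(),
            "fractions4": self.fractions4.as_dict(),
            "rmsd_delta_eps": self.rmsd_delta_eps,
            "degenerate": self.degenerate,
            "wavelengths": self.reconstructed.wavelengths.tolist(),
            "reconstructed": self.reconstructed.values.tolist(),
        }


def nnls_fit(spectrum: CDSpectrum, refset: ReferenceSet) -> tuple[np.ndarray, float]:
    """Solve min ‖C·x − b‖² s.t. x ≥ 0 by the Lawson–Hanson active-set method.

    The spectrum and reference set must share an identical wavelength grid
    (use :func:`cdrefine.refbasis.restrict_overlap` first).  Returns the
    weight vector and the squared residual Δ².
    """
    if not spectra_grids_match(spectrum, refset):
        raise ContractError("spectrum and reference set are on different grids")
    b = spectrum.values
    if np.all(b == 0):
        return np.zeros(refset.n_proteins), 0.0
    x, rnorm = scipy.optimize.nnls(refset.spectra, b)
    return x, float(rnorm**2)


def fractions_from_weights(
    weights, refset: ReferenceSet, norm: str = "l1"
) -> np.ndarray:
    """Six-category fractions d = A·x / ‖x‖ from fit weights.

    ``norm="l1"`` (default) divides by the sum of weights, making d a
    convex combination of fraction columns that sums to 1; ``norm="l2"``
    divides by the Euclidean norm instead.
    """
    x = np.asarray(weights, dtype=float)
    if x.shape != (refset.n_proteins,):
        raise ContractError(
            f"{x.size} weights for {refset.n_proteins} reference proteins"
        )
    if np.any(x < 0):
        raise ValidationError("weights must be non-negative")
    if norm == "l1":
        denom = x.sum()
    elif norm == "l2":
        denom = float(np.linalg.norm(x))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if denom <= _ZERO_WEIGHT_TOL:
        raise DegenerateFitError("all-zero weights: fractions undefined")
    return refset.fractions @ x / denom


def consolidate_six_to_four(f6) -> FourFractions:
    """Collapse six categories to four, conserving the total exactly.

    helix = helix_regular + helix_distorted; strand = strand_regular +
    strand_distorted; turn and unordered pass through.
    """
    f6 = np.asarray(f6, dtype=float)
    if f6.shape != (6,):
        raise ValidationError(f"expected 6 fractions, got shape {f6.shape}")
    if np.any(f6 < 0):
        raise ValidationError(f"negative fraction in {f6.tolist()}")
    return FourFractions(
        helix=float(f6[0] + f6[1]),
        strand=float(f6[2] + f6[3]),
        turn=float(f6[4]),
        unordered=float(f6[5]),
    )


def reconstruct(weights, refset: ReferenceSet) -> CDSpectrum:
    """Reconstructed spectrum C·x on the reference grid."""
    x = np.asarray(weights, dtype=float)
    if x.shape != (refset.n_proteins,):
        raise ContractError(
            f"{x.size} weights for {refset.n_proteins} reference proteins"
        )
    return CDSpectrum(refset.wavelengths, refset.spectra @ x, label="reconstructed")


def fit_rmsd(observed: CDSpectrum, reconstructed: CDSpectrum) -> float:
    """RMS deviation between two spectra on the same grid (M⁻¹cm⁻¹)."""
    if not spectra_grids_match(observed, reconstructed):
        raise ContractError("spectra are on different wavelength grids")
    diff = observed.values - reconstructed.values
    return float(np.sqrt(np.mean(diff**2)))


def deconvolute(
    spectrum: CDSpectrum,
    refset: ReferenceSet,
    window: tuple[float, float] | None = (190.0, 240.0),
    norm: str = "l1",
) -> DeconvolutionResult:
    """Full NN-LSQ deconvolution of a CD spectrum against a reference basis.

    Restricts both inputs to the common grid inside ``window`` (default
    190–240 nm, endpoints inclusive), fits non-negative weights, converts
    them to six- and four-category secondary-structure fractions, and
    reports the reconstructed spectrum and its RMSD in Δε.  Deterministic
    for fixed inputs.  An all-zero spectrum yields a degenerate result with
    zero weights and uniform-NaN-free zero fractions flagged via
    ``degenerate=True``.
    """
    spec, sub = restrict_overlap(spectrum, refset, window)
    weights, residual_sq = nnls_fit(spec, sub)
    recon = reconstruct(weights, sub)
    rmsd = fit_rmsd(spec, recon)
    if weights.sum() <= _ZERO_WEIGHT_TOL:
        zero6 = np.zeros(6)
        return DeconvolutionResult(
            weights=weights,
            residual_sq=residual_sq,
            fractions6=zero6,
            fractions4=FourFractions(0.0, 0.0, 0.0, 0.0),
            reconstructed=recon,
            rmsd_delta_eps=rmsd,
            degenerate=True,
        )
    f6 = fractions_from_weights(weights, sub, norm=norm)
    if norm == "l1":
        f4 = consolidate_six_to_four(f6)
    else:
        # L2-normalized fractions sum to ||x||1/||x||2 >= 1; skip the
        # unit-sum invariant but keep the same pairwise consolidation.
        f4 = FourFractions.unchecked(
            [f6[0] + f6[1], f6[2] + f6[3], f6[4], f6[5]]
        )
    return DeconvolutionResult(
        weights=weights,
        residual_sq=residual_sq,
        fractions6=f6,
        fractions4=f4,
        reconstructed=recon,
        rmsd_delta_eps=rmsd,
    )


__all__ = [
    "FourFractions",
    "DeconvolutionResult",
    "nnls_fit",
    "fractions_from_weights",
    "consolidate_six_to_four",
    "reconstruct",
    "fit_rmsd",
    "deconvolute",
]
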