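"""Seeded synthetic inputs for every pipeline stage.

Everything the refinement pipeline consumes can be generated here
deterministically: a reference basis set with known fraction vectors, noisy
mixture spectra with known ground truth, per-frame secondary-structure
assignment strings with a prescribed ensemble-average composition, and toy
multi-model peptide coordinates with prescribed contact geometry.  A single
integer seed threads through all sub-generators via a splittable
``numpy.random.SeedSequence`` scheme, so every output is bit-reproducible
per seed and the sub-generators stay independent.

The CD band-shape templates are fixed constants with the qualitative
morphology of far-UV protein CD — a helix-like pair of negative bands near
208/222 nm with a strong positive band near 192 nm, a strand-like
positive/negative couplet near 196/218 nm, and the deep ~198 nm negative
band of unordered chains — not fits to any real reference data.  Only the
morphology matters: the generators exist so that deconvolution, selection
and contact analysis can be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
import zlib

import numpy as np

from .contacts import DonorAcceptorAnnotation, infer_backbone_polar
from .deconv import FourFractions, consolidate_six_to_four
from .ensemble import AssignmentTrajectory
from .errors import ContractError, ValidationError
from .refbasis import CDSpectrum, ReferenceSet


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs for the synthetic generators.

    ``wavelength_window`` is inclusive at both ends with 1 nm spacing;
    ``noise_sigma`` is in Δε units (M⁻¹cm⁻¹); ``target_fractions`` steers
    the assignment-trajectory generator's stationary composition (default:
    a disorder-dominated peptide, mostly unordered with minor strand/turn
    content).
    """

    seed: int = 0
    n_references: int = 48
    wavelength_window: tuple[float, float] = (190.0, 240.0)
    noise_sigma: float = 0.0
    n_frames: int = 5000
    n_residues: int = 20
    n_models: int = 20
    target_fractions: FourFractions = field(
        default_factory=lambda: FourFractions(0.04, 0.15, 0.09, 0.72)
    )

    def __post_init__(self):
        if self.n_references < 1 or self.n_frames < 1 or self.n_residues < 1:
            raise ValidationError("counts must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_window
        return np.arange(lo, hi + 0.5, 1.0)

    def child_rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named sub-stream of the master seed."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Reference basis
# ---------------------------------------------------------------------------

def _gauss(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


#: (amplitude Δε, center nm, width nm) triples per six-category template.
_BAND_SHAPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "helix_regular": ((28.0, 192.0, 5.0), (-10.5, 209.0, 6.0), (-11.0, 222.0, 7.0)),
    "helix_distorted": ((14.0, 193.0, 6.0), (-5.5, 207.0, 7.0), (-4.5, 221.0, 8.0)),
    "strand_regular": ((11.0, 196.0, 6.0), (-7.5, 218.0, 8.0)),
    "strand_distorted": ((5.0, 198.0, 7.0), (-3.5, 216.0, 9.0)),
    "turn": ((3.5, 205.0, 8.0), (-2.0, 222.0, 10.0)),
    "unordered": ((-16.0, 197.0, 7.0), (1.5, 222.0, 12.0)),
}

#: Dirichlet concentration per category, skewed toward unordered to mimic
#: a soluble-and-denatured reference population.
_DIRICHLET_ALPHA = np.array([0.6, 0.4, 0.7, 0.5, 0.9, 2.0])


def band_templates(wavelengths: np.ndarray) -> np.ndarray:
    """Six fixed band-shape templates, one row per six-category structure."""
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros((6, wl.size))
    for i, cat in enumerate(
        ("helix_regular", "helix_distorted", "strand_regular",
         "strand_distorted", "turn", "unordered")
    ):
        for amp, mu, sigma in _BAND_SHAPES[cat]:
            out[i] += amp * _gauss(wl, mu, sigma)
    return out


def make_reference_set(config: GeneratorConfig) -> ReferenceSet:
    """Synthetic reference basis with known fraction vectors.

    Each reference spectrum is its fraction vector applied to the six band
    templates, plus a small smooth per-protein perturbation (three seeded
    Gaussian bumps, ~0.5 Δε) that makes the columns linearly independent —
    without it all spectra would live in the templates' 6-dimensional span
    and weight recovery would be ill-posed.
    """
    if config.n_references < 2:
        warnings.warn(
            "a reference set with < 2 proteins is degenerate for fitting",
            stacklevel=2,
        )
    rng = config.child_rng("refset")
    wl = config.wavelengths()
    templates = band_templates(wl)
    fractions = rng.dirichlet(_DIRICHLET_ALPHA, size=config.n_references).T
    spectra = templates.T @ fractions
    lo, hi = config.wavelength_window
    for k in range(config.n_references):
        for _ in range(3):
            amp = rng.normal(0.0, 0.5)
            mu = rng.uniform(lo, hi)
            sigma = rng.uniform(3.0, 8.0)
            spectra[:, k] += amp * _gauss(wl, mu, sigma)
    names = tuple(f"SYN{k + 1:02d}" for k in range(config.n_references))
    return ReferenceSet(wl, spectra, fractions, names)


def make_mixture_spectrum(
    refset: ReferenceSet,
    weights,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[CDSpectrum, FourFractions]:
    """Mixture spectrum C·w plus seeded Gaussian noise, with ground truth.

    The ground truth is the consolidated four-category fraction vector
    A·w / ‖w‖₁ that a perfect deconvolution of the noiseless mixture would
    return.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (refset.n_proteins,):
        raise ContractError(
            f"{w.size} weights for {refset.n_proteins} reference proteins"
        )
    if np.any(w < 0) or not np.any(w > 0):
        raise ContractError("weights must be non-negative with at least one > 0")
    rng = np.random.default_rng(seed)
    values = refset.spectra @ w
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    truth6 = refset.fractions @ w / w.sum()
    return (
        CDSpectrum(refset.wavelengths, values, label="synthetic mixture"),
        consolidate_six_to_four(truth6),
    )


# ---------------------------------------------------------------------------
# Assignment trajectories
# ---------------------------------------------------------------------------

#: One representative emission code per category (all map through the
#: default code table to their own category).
_CATEGORY_CODES = np.array(["H", "E", "T", "C"])

#: Per-step probability of redrawing a residue's category from the target
#: distribution (1 − this is the persistence of the per-residue chain).
_CHAIN_REDRAW_P = 0.25


def make_assignment_trajectory(config: GeneratorConfig) -> AssignmentTrajectory:
    """Per-frame per-residue codes from independent per-residue Markov chains.

    Each residue's category follows a stationary chain that keeps its state
    with probability 1 − 0.25 and otherwise redraws from
    ``config.target_fractions``, so the stationary (and ensemble-average)
    composition equals the target while frames stay temporally correlated
    like a real trajectory.
    """
    p = config.target_fractions.as_array()
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"target fractions sum to {p.sum():.8f}, not 1")
    rng = config.child_rng("ssa")
    n_f, n_r = config.n_frames, config.n_residues
    states = rng.choice(4, size=n_r, p=p)
    frames = []
    for _ in range(n_f):
        frames.append("".join(_CATEGORY_CODES[states]))
        redraw = rng.random(n_r) < _CHAIN_REDRAW_P
        if np.any(redraw):
            states = np.where(redraw, rng.choice(4, size=n_r, p=p), states)
    return AssignmentTrajectory(frames=tuple(frames), n_residues=n_r)


# ---------------------------------------------------------------------------
# Toy coordinate ensembles
# ---------------------------------------------------------------------------

#: Ideal-helix cylindrical placement (radius Å, phase offset deg, rise
#: offset Å) per backbone atom, 100°/residue twist and 1.5 Å/residue rise.
_HELIX_ATOM_CYL = {
    "N": (1.60, -28.0, -0.90),
    "CA": (2.27, 0.0, 0.0),
    "CB": (3.30, 10.0, -0.50),
    "C": (1.70, 26.0, 0.45),
    "O": (2.00, 27.0, 1.70),
}

_MODEL_JITTER_SIGMA = 0.15   # Å, per-atom Gaussian jitter across models


def _helix_coords(n_res: int) -> dict[str, np.ndarray]:
    coords: dict[str, np.ndarray] = {}
    i = np.arange(n_res)
    for name, (r, phase, dz) in _HELIX_ATOM_CYL.items():
        theta = np.deg2rad(100.0 * i + phase)
        coords[name] = np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), 1.5 * i + dz]
        )
    return coords


def _hairpin_coords(n_res: int) -> dict[str, np.ndarray]:
    # Two antiparallel strands: residue i (first half) faces residue
    # n-1-i (second half) across a 4.6 Å sheet gap; carbonyl O and amide
    # N/H point into the gap so i <-> n-1-i hydrogen bonds form.
    half = n_res // 2
    ca = np.zeros((n_res, 3))
    strand = np.zeros(n_res, dtype=int)
    for i in range(n_res):
        if i < half:
            ca[i] = (3.5 * i, 0.0, 0.0)
        else:
            strand[i] = 1
            ca[i] = (3.5 * (n_res - 1 - i), 4.6, 0.0)
    # turn apex: lift the middle residue(s) out of plane
    for i in range(half - (n_res % 2 == 0), half + 1):
        ca[i, 2] += 1.5
    inward = np.where(strand == 0, 1.0, -1.0)   # +y for strand A, -y for B
    coords = {
        "N": ca + np.column_stack([np.full(n_res, -1.2), 0.4 * inward, np.zeros(n_res)]),
        "CA": ca,
        "CB": ca + np.array([0.0, 0.0, 1.5]),
        "C": ca + np.column_stack([np.full(n_res, 1.2), 0.4 * inward, np.zeros(n_res)]),
        "O": ca + np.column_stack([np.full(n_res, 1.2), 1.55 * inward, np.zeros(n_res)]),
    }
    return coords


def _coil_coords(n_res: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    # Self-avoiding random walk of CA positions, step 3.8 Å.
    ca = np.zeros((n_res, 3))
    for i in range(1, n_res):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = ca[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(ca[: i - 1] - cand, axis=1)) > 4.5:
                ca[i] = cand
                break
        else:
            ca[i] = ca[i - 1] + np.array([3.8, 0.0, 0.0])
    offs = {
        "N": np.array([-1.2, 0.5, 0.3]),
        "CB": np.array([0.0, -1.0, 1.2]),
        "C": np.array([1.2, 0.5, -0.3]),
        "O": np.array([1.4, 1.6, -0.3]),
    }
    coords = {"CA": ca}
    for name, off in offs.items():
        coords[name] = ca + off
    return coords


def _place_amide_h(coords: dict[str, np.ndarray], motif: str, n_res: int) -> np.ndarray:
    # Toy amide hydrogen: sit 1.0 Å from N, aimed at the acceptor the motif
    # intends (O of i-4 in a helix, O of the facing residue in a hairpin),
    # which gives near-linear N-H...O geometry by construction.
    N, O = coords["N"], coords["O"]
    H = np.empty((n_res, 3))
    for i in range(n_res):
        if motif == "helix" and i >= 4:
            aim = O[i - 4] - N[i]
        elif motif == "hairpin":
            aim = O[n_res - 1 - i] - N[i]
        else:
            aim = N[i] - coords["CA"][i]
        norm = np.linalg.norm(aim)
        if norm == 0:
            aim, norm = np.array([0.0, 0.0, 1.0]), 1.0
        H[i] = N[i] + aim / norm
    return H


def make_toy_ensemble(
    config: GeneratorConfig, motif: str = "hairpin"
):
    """Multi-model toy polypeptide with prescribed contact geometry.

    Motifs: ``hairpin`` (residues i and n−1−i in backbone contact across an
    antiparallel sheet gap), ``helix`` (i, i+4 contacts and i→i−4 backbone
    hydrogen bonds) and ``coil`` (independent self-avoiding walks per
    model, no persistent contacts).  Residues are alanines with atoms N,
    H, CA, CB, C, O; models add per-atom Gaussian jitter (hairpin/helix)
    or fresh walks (coil).  Returns ``(AtomArrayStack, annotation)`` where
    the annotation marks every backbone amide N–H as donor and every
    carbonyl O as acceptor.
    """
    import biotite.structure as struc

    if config.n_residues < 4:
        raise ValidationError("toy ensembles need >= 4 residues")
    if motif not in ("hairpin", "helix", "coil"):
        raise ValueError(f"unknown motif {motif!r}")
    rng = config.child_rng(f"ensemble-{motif}")
    n_res = config.n_residues
    atom_order = ("N", "H", "CA", "CB", "C", "O")
    elements = {"N": "N", "H": "H", "CA": "C", "CB": "C", "C": "C", "O": "O"}

    models = []
    for _ in range(config.n_models):
        if motif == "coil":
            base = _coil_coords(n_res, rng)
            base["H"] = _place_amide_h(base, motif, n_res)
            coords = base
        else:
            base = _helix_coords(n_res) if motif == "helix" else _hairpin_coords(n_res)
            base["H"] = _place_amide_h(base, motif, n_res)
            coords = {
                k: v + rng.normal(0.0, _MODEL_JITTER_SIGMA, size=v.shape)
                for k, v in base.items()
            }
        atoms = struc.AtomArray(n_res * len(atom_order))
        k = 0
        for i in range(n_res):
            for name in atom_order:
                atoms.coord[k] = coords[name][i]
                atoms.atom_name[k] = name
                atoms.element[k] = elements[name]
                atoms.res_id[k] = i + 1
                atoms.res_name[k] = "ALA"
                atoms.chain_id[k] = "A"
                atoms.hetero[k] = False
                k += 1
        models.append(atoms)
    stack = struc.stack(models)
    return stack, infer_backbone_polar(stack)


__all__ = [
    "GeneratorConfig",
    "band_templates",
    "make_reference_set",
    "make_mixture_spectrum",
    "make_assignment_trajectory",
    "make_toy_ensemble",
]
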