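"""Residue-pair contact and hydrogen-bond probability maps.

A refined ensemble (multi-model coordinates, all models on one topology) is
summarized by residue × residue probability matrices under three geometric
contact definitions:

1. *any_atom*: residues i and j (|i − j| ≥ 4 by default) are in contact in
   a model when any atom of i lies within 4 Å of any atom of j.
2. *backbone* / *sidechain*: as (1) but restricted to backbone atoms
   (N, CA, C, O plus terminal oxygens) or to side-chain atoms.  Glycine,
   which has no heavy side-chain atom, contributes its α-hydrogen as its
   side chain.
3. *hbond*: a donor heavy atom D of residue i with bonded hydrogen H forms
   a hydrogen bond to an acceptor A of residue j when the D–A distance is
   within 4 Å and the D–H···A geometry deviates from linearity by at most
   30° (angle at H ≥ 150°).  The minimum sequence separation defaults to 2
   here, since short-range (i, i±3) hydrogen bonds are structurally
   meaningful.

Each map entry is the fraction of models in which the contact exists;
hydrogen-bond maps are conventionally max-scaled so the strongest bond has
probability exactly 1.

Ensembles are biotite ``AtomArrayStack`` objects (multi-model PDB via
``biotite.structure.io.pdb``); donor/acceptor annotations are explicit atom
indices, inferable for backbone amides with :func:`infer_backbone_polar`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AnnotationError, ContractError, ValidationError

#: Heavy backbone atoms (terminal oxygen variants included).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})

#: Hydrogens riding on the backbone (excluded from side chains, except GLY).
BACKBONE_HYDROGENS = frozenset({"H", "HN", "H1", "H2", "H3", "HA", "HA1", "HA2", "HA3"})

#: Glycine α-hydrogens counted as its side chain.
_GLY_SIDECHAIN_H = frozenset({"HA", "HA1", "HA2", "HA3"})

MODES = ("any_atom", "backbone", "sidechain", "hbond")


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds for contact / hydrogen-bond detection.

    ``distance_cutoff`` in Å; ``min_separation`` in residue indices;
    ``angle_cutoff`` in degrees of deviation from D–H···A linearity
    (only used in hbond mode).
    """

    distance_cutoff: float = 4.0
    min_separation: int = 4
    angle_cutoff: float = 30.0
    mode: str = "any_atom"

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValidationError("distance_cutoff must be > 0")
        if not (0 <= self.angle_cutoff <= 90):
            raise ValidationError("angle_cutoff must be in [0, 90] degrees")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be >= 0")
        if self.mode not in MODES:
            raise ValidationError(f"mode {self.mode!r} not in {MODES}")

    @classmethod
    def hbond(cls, distance_cutoff: float = 4.0, angle_cutoff: float = 30.0,
              min_separation: int = 2) -> "ContactCriteria":
        """Hydrogen-bond defaults (separation ≥ 2 rather than the contact ≥ 4)."""
        return cls(distance_cutoff=distance_cutoff, min_separation=min_separation,
                   angle_cutoff=angle_cutoff, mode="hbond")


@dataclass(frozen=True)
class ResiduePairMap:
    """Symmetric residue × residue probability matrix."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    flavor: str
    scaled: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValidationError(f"matrix shape {m.shape} for {n} labels")
        if not np.allclose(m, m.T):
            raise ValidationError("matrix must be symmetric")
        if np.any(m < 0) or np.any(m > 1 + 1e-12):
            raise ValidationError("entries must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    def scale_to_max(self) -> "ResiduePairMap":
        """Divide by the maximum entry so the strongest contact is exactly 1."""
        peak = float(self.matrix.max())
        if peak <= 0:
            return replace(self, scaled=True)
        m = self.matrix / peak
        i, j = np.unravel_index(int(np.argmax(self.matrix)), self.matrix.shape)
        m[i, j] = m[j, i] = 1.0   # guard against roundoff at the peak
        return replace(self, matrix=m, scaled=True)


# ---------------------------------------------------------------------------
# Topology helpers
# ---------------------------------------------------------------------------

def _as_stack(models):
    """Accept an AtomArrayStack or a list of AtomArrays sharing one topology."""
    if isinstance(models, (list, tuple)):
        import biotite.structure as struc

        first = models[0]
        for k, arr in enumerate(models[1:], start=1):
            if arr.array_length() != first.array_length() or not np.array_equal(
                arr.atom_name, first.atom_name
            ):
                raise ContractError(f"model {k} topology differs from model 0")
        return struc.stack(models)
    return models


def _residue_structure(models) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(coords (m, n_atoms, 3), per-atom residue index, residue labels)."""
    coords = np.asarray(models.coord, dtype=float)
    if coords.ndim != 3:
        raise ContractError("expected an AtomArrayStack (multi-model ensemble)")
    res_ids = np.asarray(models.res_id)
    res_names = np.asarray(models.res_name)
    # contiguous residue index in order of first appearance
    _, first = np.unique(res_ids, return_index=True)
    ordered = res_ids[np.sort(first)]
    index_of = {rid: k for k, rid in enumerate(ordered)}
    atom_res = np.array([index_of[r] for r in res_ids])
    labels = tuple(
        f"{res_names[np.argmax(res_ids == rid)]}{rid}" for rid in ordered
    )
    return coords, atom_res, labels


def _atom_mask(models, mode: str) -> np.ndarray:
    names = np.asarray(models.atom_name)
    res_names = np.asarray(models.res_name)
    if mode == "any_atom":
        return np.ones(names.shape, dtype=bool)
    in_bb = np.isin(names, list(BACKBONE_ATOMS))
    if mode == "backbone":
        return in_bb
    if mode == "sidechain":
        bb_h = np.isin(names, list(BACKBONE_HYDROGENS))
        mask = ~in_bb & ~bb_h
        gly_ha = (res_names == "GLY") & np.isin(names, list(_GLY_SIDECHAIN_H))
        return mask | gly_ha
    raise ValidationError(f"mode {mode!r} is not a distance-contact mode")


def contact_map(models, criteria: ContactCriteria | None = None) -> ResiduePairMap:
    """Ensemble contact probability map under definition 1 or 2.

    Entry (i, j) is the fraction of models in which at least one qualifying
    atom pair between residues i and j (|i − j| ≥ ``min_separation``) lies
    within ``distance_cutoff``.
    """
    criteria = criteria or ContactCriteria()
    if criteria.mode == "hbond":
        raise ContractError("use hbond_map for hydrogen-bond maps")
    models = _as_stack(models)
    coords, atom_res, labels = _residue_structure(models)
    mask = _atom_mask(models, criteria.mode)
    sel_res = atom_res[mask]
    n_res = len(labels)
    n_models = coords.shape[0]
    counts = np.zeros((n_res, n_res))
    res_atoms = [np.nonzero(sel_res == r)[0] for r in range(n_res)]
    for m in range(n_models):
        xyz = coords[m][mask]
        d = cdist(xyz, xyz)
        for i in range(n_res):
            ai = res_atoms[i]
            if ai.size == 0:
                continue
            for j in range(i + criteria.min_separation, n_res):
                aj = res_atoms[j]
                if aj.size == 0:
                    continue
                if d[np.ix_(ai, aj)].min() <= criteria.distance_cutoff:
                    counts[i, j] += 1
                    counts[j, i] += 1
    return ResiduePairMap(counts / n_models, labels, flavor=criteria.mode)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DonorAcceptorAnnotation:
    """Explicit H-bond chemistry: (donor, hydrogen) atom-index pairs and
    acceptor atom indices, all into the ensemble's atom order."""

    donors: tuple[tuple[int, int], ...]
    acceptors: tuple[int, ...]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"donors": [list(p) for p in self.donors],
             "acceptors": list(self.acceptors)}
        ))

    @classmethod
    def load(cls, path: str | Path) -> "DonorAcceptorAnnotation":
        doc = json.loads(Path(path).read_text())
        return cls(
            donors=tuple((int(d), int(h)) for d, h in doc["donors"]),
            acceptors=tuple(int(a) for a in doc["acceptors"]),
        )


def infer_backbone_polar(models) -> DonorAcceptorAnnotation:
    """Backbone amide N–H donors and carbonyl O acceptors from atom names.

    Residues whose N has no resolvable amide hydrogen (H/HN/H1) are skipped;
    use an explicit annotation for structures without hydrogens.
    """
    names = np.asarray(models.atom_name)
    res_ids = np.asarray(models.res_id)
    donors = []
    acceptors = []
    for rid in np.unique(res_ids):
        idx = np.nonzero(res_ids == rid)[0]
        local = {names[k]: int(k) for k in idx}
        if "N" in local:
            h = next((local[n] for n in ("H", "HN", "H1") if n in local), None)
            if h is not None:
                donors.append((local["N"], h))
        for oname in ("O", "OXT", "OT1", "OT2"):
            if oname in local:
                acceptors.append(local[oname])
    if not donors:
        raise AnnotationError("no donor with an attached hydrogen found")
    return DonorAcceptorAnnotation(tuple(donors), tuple(acceptors))


def hbond_map(
    models,
    annotation: DonorAcceptorAnnotation,
    criteria: ContactCriteria | None = None,
    scale: bool = True,
) -> ResiduePairMap:
    """Ensemble hydrogen-bond probability map (definition 3).

    A bond exists in a model when the donor–acceptor distance is within
    ``distance_cutoff`` and the D–H···A angle deviates from linearity by at
    most ``angle_cutoff`` (i.e. the angle at H is ≥ 180° − cutoff).  Entry
    (i, j) is the fraction of models with ≥ 1 bond between residues i and j
    in either direction; ``scale=True`` max-normalizes the map.
    """
    criteria = criteria or ContactCriteria.hbond()
    models = _as_stack(models)
    coords, atom_res, labels = _residue_structure(models)
    n_atoms = coords.shape[1]
    for d, h in annotation.donors:
        if not (0 <= h < n_atoms):
            raise AnnotationError(f"donor atom {d} has invalid hydrogen index {h}")
    n_res = len(labels)
    n_models = coords.shape[0]
    cos_min = np.cos(np.deg2rad(180.0 - criteria.angle_cutoff))
    counts = np.zeros((n_res, n_res))
    don = np.array([d for d, _ in annotation.donors], dtype=int)
    hyd = np.array([h for _, h in annotation.donors], dtype=int)
    acc = np.array(annotation.acceptors, dtype=int)
    for m in range(n_models):
        xyz = coords[m]
        bonded = np.zeros((n_res, n_res), dtype=bool)
        # D-A distances, all donors x acceptors at once
        dda = cdist(xyz[don], xyz[acc])
        within = dda <= criteria.distance_cutoff
        for di, ai in zip(*np.nonzero(within)):
            ri, rj = atom_res[don[di]], atom_res[acc[ai]]
            if abs(int(ri) - int(rj)) < criteria.min_separation:
                continue
            hd = xyz[don[di]] - xyz[hyd[di]]
            ha = xyz[acc[ai]] - xyz[hyd[di]]
            denom = np.linalg.norm(hd) * np.linalg.norm(ha)
            if denom == 0:
                continue
            cos_dha = float(hd @ ha) / denom
            # angle at H >= 180 - cutoff  <=>  cos(DHA) <= cos(180 - cutoff)
            if cos_dha <= cos_min:
                bonded[ri, rj] = bonded[rj, ri] = True
        counts += bonded
    pmap = ResiduePairMap(counts / n_models, labels, flavor="hbond")
    return pmap.scale_to_max() if scale else pmap


# ---------------------------------------------------------------------------
# Map I/O
# ---------------------------------------------------------------------------

def write_map(
    pair_map: ResiduePairMap | tuple[ResiduePairMap, ResiduePairMap],
    path: str | Path,
    layout: str = "matrix_csv",
) -> None:
    """Write a map as labelled CSV.

    ``matrix_csv`` writes one symmetric matrix.  ``upper_lower_split``
    takes a pair ``(upper, lower)`` of equal-shape maps and writes a
    combined matrix with the first map above and the second below the
    diagonal (diagonal zero) — the two-flavor figure convention.
    """
    path = Path(path)
    if layout == "matrix_csv":
        if not isinstance(pair_map, ResiduePairMap):
            raise ContractError("matrix_csv layout takes a single map")
        _write_matrix(pair_map.matrix, pair_map.labels, path)
    elif layout == "upper_lower_split":
        try:
            upper, lower = pair_map
        except TypeError:
            raise ContractError("upper_lower_split takes a (upper, lower) pair") from None
        if upper.matrix.shape != lower.matrix.shape:
            raise ContractError(
                f"shape mismatch {upper.matrix.shape} vs {lower.matrix.shape}"
            )
        combined = np.triu(upper.matrix, k=1) + np.tril(lower.matrix, k=-1)
        _write_matrix(combined, upper.labels, path)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _write_matrix(matrix: np.ndarray, labels, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")


def read_map(path: str | Path, flavor: str = "contact") -> ResiduePairMap:
    """Read a matrix_csv map back (round-trip inverse of :func:`write_map`)."""
    lines = Path(path).read_text().splitlines()
    labels = tuple(lines[0].split(",")[1:])
    rows = [[float(v) for v in ln.split(",")[1:]] for ln in lines[1:] if ln]
    return ResiduePairMap(np.asarray(rows), labels, flavor=flavor)


def plot_map(pair_map: ResiduePairMap, path: str | Path, title: str = "") -> None:
    """Render a map as a heat-map image (matplotlib, Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pair_map.matrix, origin="lower", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(pair_map.labels)))
    ax.set_yticks(range(len(pair_map.labels)))
    ax.set_xticklabels(pair_map.labels, rotation=90, fontsize=6)
    ax.set_yticklabels(pair_map.labels, fontsize=6)
    ax.set_title(title or pair_map.flavor)
    fig.colorbar(im, ax=ax, label="probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "BACKBONE_ATOMS",
    "MODES",
    "ContactCriteria",
    "ResiduePairMap",
    "DonorAcceptorAnnotation",
    "contact_map",
    "hbond_map",
    "infer_backbone_polar",
    "write_map",
    "read_map",
    "plot_map",
]
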