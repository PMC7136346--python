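"""Contact / hydrogen-bond probability maps against naive oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cdrefine as cdr
from cdrefine.contacts import BACKBONE_ATOMS
from cdrefine.errors import AnnotationError, ContractError, ValidationError

from conftest import make_stack


def naive_contact_oracle(stack, mode, cutoff, minsep):
    """Pure-Python all-pairs contact probabilities."""
    names = np.asarray(stack.atom_name)
    res_names = np.asarray(stack.res_name)
    res_ids = np.asarray(stack.res_id)
    residues = sorted(set(int(r) for r in res_ids))
    rid_index = {r: k for k, r in enumerate(residues)}
    n_res = len(residues)

    def keep(k):
        if mode == "any_atom":
            return True
        is_bb = names[k] in BACKBONE_ATOMS
        if mode == "backbone":
            return is_bb
        if names[k] in ("H", "HN", "H1", "H2", "H3", "HA", "HA1", "HA2", "HA3"):
            return res_names[k] == "GLY" and names[k].startswith("HA")
        return not is_bb

    counts = np.zeros((n_res, n_res))
    n_models = stack.stack_depth()
    for m in range(n_models):
        xyz = np.asarray(stack.coord[m])
        for i in range(n_res):
            for j in range(i + minsep, n_res):
                hit = False
                for a in range(len(names)):
                    if rid_index[int(res_ids[a])] != i or not keep(a):
                        continue
                    for b in range(len(names)):
                        if rid_index[int(res_ids[b])] != j or not keep(b):
                            continue
                        if np.linalg.norm(xyz[a] - xyz[b]) <= cutoff:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    counts[i, j] += 1
                    counts[j, i] += 1
    return counts / n_models


def naive_hbond_oracle(stack, annotation, cutoff, angle_cutoff, minsep):
    res_ids = np.asarray(stack.res_id)
    residues = sorted(set(int(r) for r in res_ids))
    rid_index = {r: k for k, r in enumerate(residues)}
    n_res = len(residues)
    counts = np.zeros((n_res, n_res))
    for m in range(stack.stack_depth()):
        xyz = np.asarray(stack.coord[m])
        bonded = np.zeros((n_res, n_res), dtype=bool)
        for (d, h) in annotation.donors:
            for a in annotation.acceptors:
                ri = rid_index[int(res_ids[d])]
                rj = rid_index[int(res_ids[a])]
                if abs(ri - rj) < minsep:
                    continue
                if np.linalg.norm(xyz[d] - xyz[a]) > cutoff:
                    continue
                v1 = xyz[d] - xyz[h]
                v2 = xyz[a] - xyz[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle >= 180.0 - angle_cutoff:
                    bonded[ri, rj] = bonded[rj, ri] = True
        counts += bonded
    return counts / stack.stack_depth()


def two_residue_stack(distance, sep=4):
    """First and last of sep+1 residues `distance` apart, the rest far away."""
    n = sep + 1
    coords = [[0.0, 100.0 * i, 0.0] for i in range(n)]
    coords[0] = [0.0, 0.0, 0.0]
    coords[-1] = [distance, 0.0, 0.0]
    return make_stack([coords], ["CA"] * n, list(range(1, n + 1)))


def test_contact_within_cutoff_probability_one():
    stack = two_residue_stack(3.9)
    pmap = cdr.contact_map(stack, cdr.ContactCriteria())
    assert pmap.matrix[0, -1] == 1.0


def test_contact_beyond_cutoff_zero():
    stack = two_residue_stack(4.1)
    pmap = cdr.contact_map(stack, cdr.ContactCriteria())
    assert pmap.matrix[0, -1] == 0.0


def test_separation_rule_suppresses_close_neighbors():
    # residues i and i+3 at 1 Å: below the 4-residue separation -> 0
    stack = make_stack(
        [[[0, 0, 0], [100, 0, 0], [200, 0, 0], [1.0, 0, 0]]],
        ["CA"] * 4, [1, 2, 3, 4],
    )
    pmap = cdr.contact_map(stack, cdr.ContactCriteria(min_separation=4))
    assert pmap.matrix[0, 3] == 0.0
    pmap2 = cdr.contact_map(stack, cdr.ContactCriteria(min_separation=3))
    assert pmap2.matrix[0, 3] == 1.0


@pytest.mark.parametrize("mode", ["any_atom", "backbone", "sidechain"])
def test_contact_map_matches_naive_oracle(mode, rng):
    stack, _ = cdr.make_toy_ensemble(
        cdr.GeneratorConfig(seed=11, n_residues=8, n_models=10), motif="coil"
    )
    crit = cdr.ContactCriteria(mode=mode, min_separation=2)
    pmap = cdr.contact_map(stack, crit)
    oracle = naive_contact_oracle(stack, mode, 4.0, 2)
    assert np.allclose(pmap.matrix, oracle)


def test_any_atom_dominates_backbone_and_sidechain():
    stack, _ = cdr.make_toy_ensemble(
        cdr.GeneratorConfig(seed=12, n_residues=10, n_models=10), motif="hairpin"
    )
    maps = {
        m: cdr.contact_map(stack, cdr.ContactCriteria(mode=m)).matrix
        for m in ("any_atom", "backbone", "sidechain")
    }
    assert np.all(maps["any_atom"] >= np.maximum(maps["backbone"], maps["sidechain"]) - 1e-12)


def test_contact_probability_rigid_invariance():
    stack, _ = cdr.make_toy_ensemble(
        cdr.GeneratorConfig(seed=13, n_residues=8, n_models=5), motif="hairpin"
    )
    before = cdr.contact_map(stack).matrix
    R = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).as_matrix()
    moved = stack.copy()
    moved.coord = stack.coord @ R.T + np.array([10.0, -5.0, 3.0])
    after = cdr.contact_map(moved).matrix
    assert np.allclose(before, after, atol=1e-9)


def test_glycine_hydrogen_is_its_sidechain():
    # GLY has no heavy side-chain atom; its alpha hydrogen must carry the
    # side-chain contact.
    coords = [
        [0, 0, 0], [1.0, 0, 0],          # res1: CA, HA (GLY)
        [0, 100, 0],                     # res2 far away
        [0, 200, 0],                     # res3
        [3.0, 0, 0], [50, 0, 0],         # res4: CB near res1's HA, CA far
    ]
    stack = make_stack(
        [coords],
        ["CA", "HA", "CA", "CA", "CB", "CA"],
        [1, 1, 2, 3, 4, 4],
        ["GLY", "GLY", "ALA", "ALA", "ALA", "ALA"],
    )
    pmap = cdr.contact_map(stack, cdr.ContactCriteria(mode="sidechain", min_separation=3))
    assert pmap.matrix[0, 3] == 1.0   # HA(gly)-CB within 4 A


# --- hydrogen bonds --------------------------------------------------------

def hbond_fixture(angle_deg, da_dist=3.5):
    """Donor N(res1)-H and acceptor O(res5) with a prescribed DHA angle."""
    N = np.array([0.0, 0.0, 0.0])
    H = np.array([1.0, 0.0, 0.0])
    theta = np.radians(180.0 - angle_deg)  # deviation from linearity
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # bisect the H->A length so the D-A distance lands on da_dist while the
    # angle at H stays exactly angle_deg
    lo, hi = 0.0, 10.0
    for _ in range(60):
        mid = (lo + hi) / 2
        A_try = H + direction * mid
        if np.linalg.norm(A_try - N) < da_dist:
            lo = mid
        else:
            hi = mid
    A = H + direction * ((lo + hi) / 2)
    coords = [N, H, [0, 50, 0], [0, 100, 0], [0, 150, 0], A]
    stack = make_stack(
        [coords], ["N", "H", "CA", "CA", "CA", "O"], [1, 1, 2, 3, 4, 5]
    )
    ann = cdr.DonorAcceptorAnnotation(donors=((0, 1),), acceptors=(5,))
    return stack, ann


def test_hbond_accepted_near_linear():
    stack, ann = hbond_fixture(angle_deg=170.0)
    pmap = cdr.hbond_map(stack, ann, scale=False)
    assert pmap.matrix[0, 4] == 1.0


def test_hbond_rejected_bent():
    stack, ann = hbond_fixture(angle_deg=140.0)
    pmap = cdr.hbond_map(stack, ann, scale=False)
    assert pmap.matrix[0, 4] == 0.0


def test_hbond_rejected_beyond_distance():
    stack, ann = hbond_fixture(angle_deg=175.0, da_dist=4.5)
    pmap = cdr.hbond_map(stack, ann, scale=False)
    assert pmap.matrix[0, 4] == 0.0


def test_hbond_map_matches_naive_oracle():
    stack, ann = cdr.make_toy_ensemble(
        cdr.GeneratorConfig(seed=14, n_residues=8, n_models=10), motif="hairpin"
    )
    crit = cdr.ContactCriteria.hbond()
    pmap = cdr.hbond_map(stack, ann, crit, scale=False)
    oracle = naive_hbond_oracle(stack, ann, 4.0, 30.0, 2)
    assert np.allclose(pmap.matrix, oracle)


def test_hbond_scaling_max_normalizes():
    # raw probabilities {0.5, 0.25} -> scaled {1.0, 0.5}
    m = np.zeros((6, 6))
    m[0, 4] = m[4, 0] = 0.5
    m[1, 5] = m[5, 1] = 0.25
    raw = cdr.ResiduePairMap(m, tuple("abcdef"), flavor="hbond")
    scaled = raw.scale_to_max()
    assert scaled.matrix[0, 4] == 1.0
    assert scaled.matrix[1, 5] == 0.5
    assert scaled.scaled


def test_scaled_empty_map_stays_zero():
    raw = cdr.ResiduePairMap(np.zeros((3, 3)), ("a", "b", "c"), flavor="hbond")
    scaled = raw.scale_to_max()
    assert np.all(scaled.matrix == 0)


def test_hbond_invalid_hydrogen_index():
    stack, _ = hbond_fixture(angle_deg=170.0)
    bad = cdr.DonorAcceptorAnnotation(donors=((0, 99),), acceptors=(5,))
    with pytest.raises(AnnotationError):
        cdr.hbond_map(stack, bad)


def test_infer_backbone_polar_requires_hydrogens():
    stack = two_residue_stack(3.9)   # CA-only model
    with pytest.raises(AnnotationError):
        cdr.infer_backbone_polar(stack)


# --- map I/O ---------------------------------------------------------------

def test_map_symmetry_enforced():
    bad = np.zeros((3, 3))
    bad[0, 1] = 1.0
    with pytest.raises(ValidationError):
        cdr.ResiduePairMap(bad, ("a", "b", "c"), flavor="contact")


def test_write_read_roundtrip(tmp_path, rng):
    m = rng.uniform(0, 1, size=(5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    pmap = cdr.ResiduePairMap(m, tuple("abcde"), flavor="contact")
    p = tmp_path / "map.csv"
    cdr.write_map(pmap, p)
    back = cdr.read_map(p)
    assert np.allclose(back.matrix, pmap.matrix, atol=1e-9)
    assert back.labels == pmap.labels


def test_split_layout_places_flavors(tmp_path, rng):
    a = rng.uniform(0, 1, size=(4, 4)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
    b = rng.uniform(0, 1, size=(4, 4)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
    bb = cdr.ResiduePairMap(a, tuple("wxyz"), flavor="backbone")
    sc = cdr.ResiduePairMap(b, tuple("wxyz"), flavor="sidechain")
    p = tmp_path / "split.csv"
    cdr.write_map((bb, sc), p, layout="upper_lower_split")
    lines = p.read_text().splitlines()
    values = np.array([[float(v) for v in ln.split(",")[1:]] for ln in lines[1:]])
    for i in range(4):
        for j in range(4):
            if i < j:
                assert values[i, j] == pytest.approx(a[i, j], abs=1e-9)
            elif i > j:
                assert values[i, j] == pytest.approx(b[i, j], abs=1e-9)
            else:
                assert values[i, j] == 0.0


def test_split_layout_shape_mismatch(tmp_path):
    a = cdr.ResiduePairMap(np.zeros((3, 3)), ("a", "b", "c"), flavor="backbone")
    b = cdr.ResiduePairMap(np.zeros((4, 4)), tuple("wxyz"), flavor="sidechain")
    with pytest.raises(ContractError):
        cdr.write_map((a, b), tmp_path / "bad.csv", layout="upper_lower_split")
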