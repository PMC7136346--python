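"""Per-frame fractions, Eq.-style pair selection and ensemble spread."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cdrefine as cdr
from cdrefine.deconv import FourFractions
from cdrefine.errors import ContractError, MappingError, ValidationError


def brute_force_pairs(S, target, phi):
    """Independent double-loop oracle over all frame pairs."""
    n = S.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(np.abs((S[i] + S[j]) / 2 - target) < phi):
                out.append((i, j))
    return out


def random_table(rng, n):
    return cdr.FrameFractionTable(rng.dirichlet(np.ones(4), size=n))


# --- fractions_per_frame ---------------------------------------------------

def test_all_helix_frame():
    traj = cdr.AssignmentTrajectory(frames=("H" * 20,), n_residues=20)
    table = cdr.fractions_per_frame(traj)
    assert np.allclose(table.fractions[0], [1, 0, 0, 0])


def test_hand_counted_mixed_frame():
    # 3 helix, 2 strand, 1 turn, 4 coil over 10 residues
    traj = cdr.AssignmentTrajectory(frames=("HHGEETCCCC",), n_residues=10)
    table = cdr.fractions_per_frame(traj)
    assert np.allclose(table.fractions[0], [0.3, 0.2, 0.1, 0.4])


def test_unassigned_codes_count_as_unordered():
    traj = cdr.AssignmentTrajectory(frames=("H -.0",), n_residues=5)
    table = cdr.fractions_per_frame(traj)
    assert np.allclose(table.fractions[0], [0.2, 0, 0, 0.8])


def test_unknown_code_names_character_and_frame():
    traj = cdr.AssignmentTrajectory(
        frames=("HHHH", "HZHH"), n_residues=4,
        code_table={"H": "helix", "Z": "strand"},
    )
    bad = cdr.AssignmentTrajectory(frames=("HHHH", "HXHH"), n_residues=4)
    with pytest.raises(MappingError, match=r"'X'.*frame 1"):
        cdr.fractions_per_frame(bad)
    cdr.fractions_per_frame(traj)  # custom table accepted


def test_frame_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        cdr.AssignmentTrajectory(frames=("HHH", "HH"), n_residues=3)


def test_assignment_io_roundtrip(tmp_path):
    traj = cdr.make_assignment_trajectory(
        cdr.GeneratorConfig(seed=3, n_frames=50, n_residues=12)
    )
    p = tmp_path / "ss.txt"
    cdr.save_assignments(traj, p)
    back = cdr.load_assignments(p)
    assert back.frames == traj.frames


# --- select_frame_pairs ----------------------------------------------------

def test_identical_frames_matching_target_accepted():
    S0 = FourFractions(0.25, 0.25, 0.25, 0.25)
    table = cdr.FrameFractionTable(np.tile([0.25, 0.25, 0.25, 0.25], (2, 1)))
    sel = cdr.select_frame_pairs(table, cdr.SelectionCriteria(S0, phi=1e-6))
    assert sel.pairs == ((0, 1),)
    assert sel.n_frames == 2


def test_phi_zero_exact_match_only():
    table = cdr.FrameFractionTable(
        np.array([
            [0.5, 0.5, 0.0, 0.0],
            [0.1, 0.1, 0.4, 0.4],
            [0.3, 0.3, 0.2, 0.2],   # avg(0,1) == this target
        ])
    )
    target = FourFractions(0.3, 0.3, 0.2, 0.2)
    sel = cdr.select_frame_pairs(table, cdr.SelectionCriteria(target, phi=0.0))
    assert sel.pairs == ((0, 1),)   # exact-match mode keeps only exact averages
    mismatched = cdr.SelectionCriteria(FourFractions(0.4, 0.2, 0.2, 0.2), phi=0.0)
    assert cdr.select_frame_pairs(table, mismatched).pairs == ()


@pytest.mark.parametrize("strategy", ["exhaustive", "sorted_window"])
def test_selection_matches_brute_force(strategy, rng):
    table = random_table(rng, 50)
    target = FourFractions.from_array(table.fractions.mean(axis=0))
    crit = cdr.SelectionCriteria(target, phi=0.035)
    sel = cdr.select_frame_pairs(table, crit, strategy=strategy)
    assert list(sel.pairs) == brute_force_pairs(
        table.fractions, target.as_array(), 0.035
    )


def test_strategies_identical_across_random_tables(rng):
    for _ in range(10):
        table = random_table(rng, 120)
        target = FourFractions.from_array(table.fractions.mean(axis=0))
        for phi in (0.01, 0.035, 0.1):
            crit = cdr.SelectionCriteria(target, phi=phi)
            a = cdr.select_frame_pairs(table, crit, strategy="exhaustive")
            b = cdr.select_frame_pairs(table, crit, strategy="sorted_window")
            assert a.pairs == b.pairs


def test_phi_monotonicity(rng):
    table = random_table(rng, 80)
    target = FourFractions.from_array(table.fractions.mean(axis=0))
    prev: set = set()
    for phi in (0.01, 0.035, 0.1, 0.3):
        sel = cdr.select_frame_pairs(table, cdr.SelectionCriteria(target, phi=phi))
        cur = set(sel.pairs)
        assert prev <= cur
        prev = cur


def test_selection_invariant_under_frame_permutation(rng):
    table = random_table(rng, 40)
    target = FourFractions.from_array(table.fractions.mean(axis=0))
    crit = cdr.SelectionCriteria(target, phi=0.05)
    base = cdr.select_frame_pairs(table, crit)
    perm = rng.permutation(40)
    permuted = cdr.FrameFractionTable(table.fractions[perm])
    sel_p = cdr.select_frame_pairs(permuted, crit)
    # permuting frames permutes, but does not change, the pair multiset
    inv = np.empty(40, dtype=int)
    inv[perm] = np.arange(40)
    mapped = {tuple(sorted((inv[i], inv[j]))) for i, j in base.pairs}
    assert mapped == set(sel_p.pairs)


def test_selection_result_json_roundtrip(tmp_path, rng):
    table = random_table(rng, 30)
    target = FourFractions.from_array(table.fractions.mean(axis=0))
    sel = cdr.select_frame_pairs(table, cdr.SelectionCriteria(target, phi=0.1))
    p = tmp_path / "sel.json"
    sel.save(p)
    assert cdr.SelectionResult.load(p) == sel


def test_selection_needs_two_frames():
    table = cdr.FrameFractionTable(np.array([[1.0, 0, 0, 0]]))
    with pytest.raises(ContractError):
        cdr.select_frame_pairs(
            table, cdr.SelectionCriteria(FourFractions(1, 0, 0, 0), 0.1)
        )


# --- ensemble_spread -------------------------------------------------------

def test_spread_duplicated_model_is_zero(rng):
    m = rng.normal(size=(8, 3))
    mx, sd = cdr.ensemble_spread(np.stack([m, m, m]))
    assert mx == pytest.approx(0.0, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_spread_rigid_rotation_invariance(rng):
    m = rng.normal(size=(12, 3))
    R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
    rotated = m @ R.T + np.array([5.0, -3.0, 1.0])
    mx, _ = cdr.ensemble_spread(np.stack([m, rotated]))
    assert mx == pytest.approx(0.0, abs=1e-9)


def test_superposed_rmsd_matches_scipy_oracle(rng):
    # Independent oracle: scipy's own Kabsch (align_vectors) on centered
    # coordinates.
    for _ in range(5):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        ac, bc = a - a.mean(0), b - b.mean(0)
        rot, _ = Rotation.align_vectors(bc, ac)
        expected = np.sqrt(np.mean(np.sum((rot.apply(ac) - bc) ** 2, axis=1)))
        assert cdr.superposed_rmsd(a, b) == pytest.approx(expected, abs=1e-9)


def test_spread_toy_models_match_pairwise_oracle(rng):
    models = rng.normal(size=(3, 4, 3))
    mx, sd = cdr.ensemble_spread(models)
    vals = [
        cdr.superposed_rmsd(models[i], models[j])
        for i in range(3) for j in range(i + 1, 3)
    ]
    assert mx == pytest.approx(max(vals))
    assert sd == pytest.approx(np.std(vals))


def test_spread_atom_count_mismatch(rng):
    with pytest.raises(ContractError):
        cdr.superposed_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
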