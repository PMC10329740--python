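"""Superposition, Gaussian scoring, alignment and averaging."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from domcross.core_model import BackboneStructure, Provenance, SourceDB
from domcross.structure_math import (
    DegenerateInputError,
    ScoreParams,
    align_to_reference,
    average_structures,
    family_level_average,
    gaussian_score,
    group_instances,
    instance_level_averages,
    kabsch_superpose,
)
from domcross.synthgen import CORE_FOLD, DECOY_FOLD, make_fold

from conftest import helix, mapped_instance, random_rigid_transform

PARAMS = ScoreParams()


def brute_force_min_rmsd(moving, fixed, n_grid=12):
    """Independent oracle: minimize RMSD over rotation space directly.

    Coarse Euler-angle grid followed by simplex refinement; translation
    is eliminated analytically by centering both point sets.
    """
    m0 = moving - moving.mean(axis=0)
    f0 = fixed - fixed.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = m0 @ R.T - f0
        return np.sqrt((d**2).sum() / len(m0))

    angles = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best = None
    for a in angles:
        for b in angles:
            for c in angles:
                rv = Rotation.from_euler("xyz", [a, b, c]).as_rotvec()
                v = rmsd_of(rv)
                if best is None or v < best[0]:
                    best = (v, rv)
    res = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return min(best[0], res.fun)


class TestKabsch:
    def test_self_superposition_is_identity(self):
        pts = helix(10).ca
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_random_rigid_transform(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(10, 91))
            pts = rng.normal(scale=5.0, size=(n, 3))
            rot, trans = random_rigid_transform(rng)
            moved = pts @ rot.T + trans
            sup = kabsch_superpose(moved, pts)
            assert sup.rmsd < 1e-8
            np.testing.assert_allclose(sup.apply(moved), pts, atol=1e-7)

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_4_point_toys(self, seed):
        rng = np.random.default_rng(seed)
        moving = rng.normal(scale=3.0, size=(4, 3))
        fixed = rng.normal(scale=3.0, size=(4, 3))
        sup = kabsch_superpose(moving, fixed)
        oracle = brute_force_min_rmsd(moving, fixed)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(line, line)


class TestGaussianScore:
    def test_zero_distances_scores_one(self):
        assert gaussian_score([0.0] * 7, 2.0, 7) == pytest.approx(1.0)

    def test_single_distance_sigma(self):
        assert gaussian_score([2.0], 2.0, 1) == pytest.approx(np.exp(-0.5))

    def test_empty_distances(self):
        assert gaussian_score([], 2.0, 10) == 0.0

    def test_closed_form(self):
        d = np.array([0.5, 1.0, 3.0, 4.5])
        expected = np.exp(-(d**2) / (2 * 1.7**2)).sum() / 6
        assert gaussian_score(d, 1.7, 6) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_each_distance(self):
        base = [1.0, 2.0, 3.0]
        s0 = gaussian_score(base, 2.0, 3)
        for i in range(3):
            bumped = list(base)
            bumped[i] += 0.1
            assert gaussian_score(bumped, 2.0, 3) < s0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            gaussian_score([1.0], 0.0, 1)
        with pytest.raises(ValueError):
            gaussian_score([1.0, 2.0], 1.0, 1)


class TestAlignToReference:
    def test_identical_copy_scores_one(self):
        s = helix(40)
        res = align_to_reference(s, s, PARAMS)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.offset == 0 and res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_truncated_head_scores_coverage_fraction(self):
        # noise breaks the screw symmetry of the ideal helix, making the
        # planted offset the unique optimum
        n = 60
        full = helix(n, noise=0.3, seed=8)
        tail = BackboneStructure("tail", np.arange(1, n - 9), full.coords[10:].copy())
        res = align_to_reference(tail, full, PARAMS)
        assert res.offset == 10
        assert res.score == pytest.approx((n - 10) / n, abs=1e-9)

    def test_longer_query_reverses_offset_roles(self):
        n = 50
        full = helix(n, noise=0.3, seed=9)
        sub = BackboneStructure("sub", np.arange(1, 31), full.coords[15:45].copy())
        res = align_to_reference(full, sub, PARAMS)
        assert res.flipped and res.offset == 15
        assert res.score == pytest.approx(1.0, abs=1e-9)

    def test_rigidly_moved_copy_scores_one(self):
        rng = np.random.default_rng(5)
        s = helix(45)
        rot, trans = random_rigid_transform(rng)
        moved = s.transformed(rot, trans)
        res = align_to_reference(moved, s, PARAMS)
        assert res.score == pytest.approx(1.0, abs=1e-8)

    def test_helix_vs_extended_decoy_below_threshold(self):
        a = make_fold(CORE_FOLD, 90, 0.3, 1)
        b = make_fold(DECOY_FOLD, 90, 0.3, 2)
        res = align_to_reference(b, a, PARAMS)
        assert res.score < 0.6 and not res.passed

    def test_zero_residue_structure_unconstructible(self):
        with pytest.raises(ValueError):
            BackboneStructure("x", [], np.zeros((0, 4, 3)))


class TestAveraging:
    def test_identical_copies_average_to_input(self):
        s = helix(25, noise=0.1, seed=4)
        avg = average_structures([s, s, s], PARAMS)
        np.testing.assert_allclose(avg.coords, s.coords, atol=1e-9)

    def test_rigid_offset_removed_by_superposition(self):
        s = helix(25)
        shifted = s.transformed(np.eye(3), np.array([2.0, 0.0, 0.0]))
        avg = average_structures([s, shifted], PARAMS)
        np.testing.assert_allclose(avg.coords, s.coords, atol=1e-9)

    def test_symmetric_displacement_averages_to_midpoint(self):
        # CA_5 and CA_12 displaced by +/-1 Å along the line joining them,
        # in opposite senses in the two members: centroids stay equal and
        # the net torque vanishes, so the optimal mutual superposition is
        # the identity and the average is the exact midpoint
        base = helix(20, noise=0.2, seed=6)
        v = base.coords[5, 1] - base.coords[12, 1]
        v = v / np.linalg.norm(v)
        up = base.coords.copy()
        dn = base.coords.copy()
        up[5, 1] += v
        up[12, 1] -= v
        dn[5, 1] -= v
        dn[12, 1] += v
        a = BackboneStructure("a", base.residue_numbers, up)
        b = BackboneStructure("b", base.residue_numbers, dn)
        avg = average_structures([a, b], PARAMS)
        np.testing.assert_allclose(avg.coords[5, 1], base.coords[5, 1], atol=1e-7)
        np.testing.assert_allclose(avg.coords, base.coords, atol=1e-7)

    def test_superposition_invariance(self):
        rng = np.random.default_rng(9)
        members = [helix(30, noise=0.2, seed=s) for s in range(3)]
        avg1 = average_structures(members, PARAMS)
        moved = []
        for m in members:
            rot, trans = random_rigid_transform(rng)
            moved.append(m.transformed(rot, trans))
        avg2 = average_structures(moved, PARAMS)
        res = align_to_reference(avg2, avg1, PARAMS)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_output_renumbered_from_one(self):
        s = helix(10)
        avg = average_structures([s, s], PARAMS)
        np.testing.assert_array_equal(avg.residue_numbers, np.arange(1, 11))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_structures([], PARAMS)


class TestInstanceGrouping:
    def _item(self, pdb, acc, start, end, seed=0):
        sti = mapped_instance(pdb_id=pdb, start=start, end=end, uniprot=acc)
        length = end - start + 1
        return sti, helix(length, noise=0.1, seed=seed, structure_id=sti.key())

    def test_overlapping_spans_one_group(self):
        items = [
            self._item("0001", "P11940", 13, 83, 1),
            self._item("0002", "P11940", 13, 83, 2),
            self._item("0003", "P11940", 11, 87, 3),
        ]
        groups = group_instances(items)
        assert len(groups) == 1
        assert groups[0][0] == "P11940:11-87"

    def test_disjoint_spans_two_groups(self):
        items = [
            self._item("0001", "P11940", 1, 90, 1),
            self._item("0002", "P11940", 101, 190, 2),
        ]
        assert len(group_instances(items)) == 2

    def test_singleton_average_is_own_backbone(self):
        items = [self._item("0001", "P11940", 1, 40, 5)]
        ((key, avg),) = instance_level_averages(items, PARAMS)
        np.testing.assert_allclose(avg.coords, items[0][1].coords, atol=1e-12)

    def test_missing_accession_forms_singleton(self):
        sti = mapped_instance(pdb_id="0004", start=1, end=30)
        sti.uniprot_id = None
        items = [(sti, helix(30))]
        ((key, _),) = instance_level_averages(items, PARAMS)
        assert key == sti.key()


class TestFamilyAverage:
    def test_anti_bias_weighting(self):
        # folds F1/F2 are the base scaled about its centroid by (1 ± eps):
        # a pure radial perturbation, so the optimal mutual superposition
        # is the identity and the unweighted family average must be the
        # base, not the deposition-weighted mean
        base = helix(30)
        centered = base.coords - base.ca.mean(axis=0)
        eps = 0.05  # keeps all pair distances inside the refinement cutoff
        f1 = BackboneStructure("f1", base.residue_numbers, base.coords + eps * centered)
        f2 = BackboneStructure("f2", base.residue_numbers, base.coords - eps * centered)
        items = (
            [(mapped_instance(pdb_id=f"000{i}", uniprot="PA0001", start=1, end=30), f1)
             for i in range(3)]
            + [(mapped_instance(pdb_id="0009", uniprot="PB0001", start=1, end=30), f2)]
        )
        inst = instance_level_averages(items, PARAMS)
        assert len(inst) == 2
        fam = family_level_average([s for _, s in inst], PARAMS)
        np.testing.assert_allclose(fam.coords, base.coords, atol=1e-7)
        biased = (3 * f1.coords + f2.coords) / 4
        assert not np.allclose(fam.coords, biased, atol=0.05)

    def test_invariant_to_duplicating_instances_within_domain(self):
        a = helix(30, noise=0.2, seed=1)
        b = helix(30, noise=0.2, seed=2)
        def items(n_dup):
            out = [
                (mapped_instance(pdb_id=f"{i:04d}", uniprot="PA0001", start=1, end=30), a)
                for i in range(n_dup)
            ]
            out.append(
                (mapped_instance(pdb_id="9999", uniprot="PB0001", start=1, end=30), b)
            )
            return out
        fam1 = family_level_average(
            [s for _, s in instance_level_averages(items(1), PARAMS)], PARAMS
        )
        fam4 = family_level_average(
            [s for _, s in instance_level_averages(items(4), PARAMS)], PARAMS
        )
        np.testing.assert_allclose(fam1.coords, fam4.coords, atol=1e-9)

    def test_single_average_is_itself(self):
        s = helix(20)
        fam = family_level_average([s], PARAMS)
        np.testing.assert_allclose(fam.coords, s.coords, atol=1e-12)
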