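"""Q order parameter, 1-Q clustering, Rg, PMF and occupancy free energies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from chromoscape.errors import InvalidArgumentError, UndefinedResultError
from chromoscape.metrics import (QParams, ensemble_rg, hcluster,
                                 occupancy_free_energy, pmf_from_samples,
                                 q_matrix, q_similarity, radius_of_gyration)
from chromoscape.structures import Structure3D
from chromoscape.synthetic import gen_dumbbell_ensemble
from chromoscape.tracing_io import convert_units
from chromoscape.units import UNIT_NM, UNIT_REDUCED

from conftest import random_structure


class TestQSimilarity:
    def test_identical_structures_give_one(self, rng):
        s = random_structure(rng)
        assert q_similarity(s, s) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        s = random_structure(rng, n_loci=40)
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        moved = Structure3D(s.coords @ rot.T + np.array([100.0, -50.0, 3.0]),
                            UNIT_NM)
        assert q_similarity(s, moved) == pytest.approx(1.0, abs=1e-10)

    def test_single_pair_at_delta_deviation(self):
        # two loci: distances differ by exactly delta -> exp(-1/2)
        a = Structure3D(np.array([[0.0, 0, 0], [165.0, 0, 0]]), UNIT_NM)
        b = Structure3D(np.array([[0.0, 0, 0], [330.0, 0, 0]]), UNIT_NM)
        assert q_similarity(a, b) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_noise_monotonically_lowers_q(self, rng):
        s = random_structure(rng, n_loci=50)
        qs = []
        for amp in (10.0, 50.0, 200.0):
            noisy = Structure3D(
                s.coords + np.random.default_rng(3).normal(scale=amp,
                                                           size=s.coords.shape),
                UNIT_NM)
            qs.append(q_similarity(s, noisy))
        assert qs[0] > qs[1] > qs[2]

    def test_unit_system_equivalence(self, rng):
        # delta = 165 nm in nm equals delta = 1 sigma in reduced units
        a = random_structure(rng, n_loci=20)
        b = random_structure(rng, n_loci=20)
        q_nm = q_similarity(a, b, QParams.for_units(UNIT_NM))
        q_red = q_similarity(convert_units(a), convert_units(b),
                             QParams.for_units(UNIT_REDUCED))
        assert q_nm == pytest.approx(q_red, rel=1e-12)

    def test_no_coresolved_pairs_is_undefined(self):
        a = np.full((4, 3), np.nan)
        a[:2] = 0.0
        b = np.full((4, 3), np.nan)
        b[2:] = 0.0
        with pytest.raises(UndefinedResultError):
            q_similarity(Structure3D(a, UNIT_NM), Structure3D(b, UNIT_NM))

    def test_missing_aware_pair_counting(self, rng):
        # oracle: drop a locus, Q must equal the naive sum over remaining pairs
        a = random_structure(rng, n_loci=8)
        coords = random_structure(rng, n_loci=8, structure_id="b").coords
        coords[3] = np.nan
        b = Structure3D(coords, UNIT_NM)
        q = q_similarity(a, b)
        total, count = 0.0, 0
        for i in range(8):
            for j in range(i + 1, 8):
                if 3 in (i, j):
                    continue
                da = np.linalg.norm(a.coords[i] - a.coords[j])
                db = np.linalg.norm(b.coords[i] - b.coords[j])
                total += np.exp(-(da - db) ** 2 / (2 * 165.0 ** 2))
                count += 1
        assert q == pytest.approx(total / count, rel=1e-12)


class TestQMatrix:
    def test_matches_per_pair_recomputation(self, small_ensemble):
        q = q_matrix(small_ensemble)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = q_similarity(small_ensemble.structures[i],
                                        small_ensemble.structures[j])
                assert q[i, j] == pytest.approx(expected, rel=1e-10)

    def test_symmetric_unit_diagonal(self, small_ensemble):
        q = q_matrix(small_ensemble)
        assert np.allclose(q, q.T, atol=1e-12)
        assert np.allclose(np.diag(q), 1.0)


class TestHCluster:
    def test_recovers_dumbbell_classes(self):
        truth = gen_dumbbell_ensemble(120, open_fraction=0.4,
                                      missing_rate=0.05, seed=6)
        q = q_matrix(truth.ensemble)
        result = hcluster(1 - q, k=2)
        assert adjusted_rand_score(truth.labels, result.labels) >= 0.95

    def test_k_equals_n_gives_singletons(self, small_ensemble):
        q = q_matrix(small_ensemble)
        result = hcluster(1 - q, k=5)
        assert len(result.sizes()) == 5

    def test_merge_heights_non_decreasing(self, small_ensemble):
        q = q_matrix(small_ensemble)
        result = hcluster(1 - q, k=2)
        heights = result.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_larger_than_n_rejected(self, small_ensemble):
        q = q_matrix(small_ensemble)
        with pytest.raises(InvalidArgumentError):
            hcluster(1 - q, k=10)

    def test_subcluster_partitions_members(self):
        truth = gen_dumbbell_ensemble(60, open_fraction=0.5, seed=8)
        q = q_matrix(truth.ensemble)
        result = hcluster(1 - q, k=2)
        top = result.labels[result.members(1)][0]
        sub = result.subcluster(1, k=2)
        assert sub.n_structures == len(result.members(1))
        assert len(sub.sizes()) == 2


class TestRadiusOfGyration:
    def test_two_point_formula(self):
        s = Structure3D(np.array([[0.0, 0, 0], [100.0, 0, 0]]), UNIT_NM)
        assert radius_of_gyration(s) == pytest.approx(50.0)

    def test_coincident_loci_zero(self):
        s = Structure3D(np.zeros((5, 3)), UNIT_NM)
        assert radius_of_gyration(s) == 0.0

    def test_matches_brute_force(self, rng):
        s = random_structure(rng, n_loci=100, missing=0.1)
        coords = s.coords[s.resolved_mask]
        centroid = coords.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1)))
        assert radius_of_gyration(s) == pytest.approx(oracle, rel=1e-12)

    def test_too_few_resolved_undefined(self):
        coords = np.full((5, 3), np.nan)
        coords[0] = 0.0
        with pytest.raises(UndefinedResultError):
            radius_of_gyration(Structure3D(coords, UNIT_NM))


class TestPMF:
    def test_uniform_samples_flat(self, rng):
        values = rng.uniform(0, 1000, size=200_000)
        profile = pmf_from_samples(values, bin_width=100.0)
        spread = np.nanmax(profile.pmf) - np.nanmin(profile.pmf)
        assert spread < 0.05

    def test_two_state_gap_is_log_ratio(self, rng):
        values = np.concatenate([np.full(900, 10.0), np.full(100, 60.0)])
        profile = pmf_from_samples(values, bin_width=25.0)
        occupied = profile.pmf[np.isfinite(profile.pmf)]
        assert occupied.max() - occupied.min() == \
            pytest.approx(np.log(9), rel=1e-12)

    def test_bimodal_rg_shows_two_minima_and_barrier(self):
        truth = gen_dumbbell_ensemble(4000, open_fraction=0.15, seed=10)
        rg = ensemble_rg(truth.ensemble)
        profile = pmf_from_samples(rg, bin_width=50.0)
        pmf = profile.pmf
        finite = np.where(np.isfinite(pmf))[0]
        lo, hi = finite.min(), finite.max()
        interior = pmf[lo:hi + 1]
        # two local minima separated by a barrier
        minima = [i for i in range(1, len(interior) - 1)
                  if interior[i] < interior[i - 1]
                  and interior[i] <= interior[i + 1]]
        assert len(minima) >= 2
        barrier = np.nanmax(interior[minima[0]:minima[-1] + 1])
        assert barrier > interior[minima[0]]
        assert barrier > interior[minima[-1]]


class TestOccupancyFreeEnergy:
    def test_traced_counts(self):
        assert occupancy_free_energy(912, 17) == pytest.approx(3.98, abs=0.005)

    def test_simulated_counts(self):
        assert occupancy_free_energy(6275, 125) == pytest.approx(3.92, abs=0.005)

    def test_equal_counts_zero(self):
        assert occupancy_free_energy(7, 7) == 0.0

    def test_antisymmetry(self):
        assert occupancy_free_energy(400, 13) == \
            pytest.approx(-occupancy_free_energy(13, 400), rel=1e-12)

    def test_zero_count_undefined(self):
        with pytest.raises(UndefinedResultError):
            occupancy_free_energy(100, 0)
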