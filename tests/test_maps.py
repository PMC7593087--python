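"""Contact maps, Pearson-by-distance, A/B annotation."""

import numpy as np
import pytest

from chromoscape.errors import InvalidArgumentError, UndefinedResultError
from chromoscape.maps import (ContactMap, ab_annotation,
                              annotation_correlation, cutoff_map,
                              pearson_by_distance, probability_map,
                              CompartmentProfile)
from chromoscape.michrom import contact_function
from chromoscape.structures import Structure3D, TracedEnsemble
from chromoscape.units import UNIT_NM, UNIT_REDUCED
from chromoscape.tracing_io import convert_units


class _FrameEnsemble:
    """Minimal SimEnsemble-like wrapper for map construction."""

    def __init__(self, frames, units=UNIT_REDUCED):
        self.frames = frames
        self._units = units

    @property
    def units(self):
        return self._units

    def coords_array(self):
        return np.stack([f.coords for f in self.frames])


class TestProbabilityMap:
    def test_single_frame_equals_contact_function(self, reduced_frame):
        pmap = probability_map(_FrameEnsemble([reduced_frame]))
        coords = reduced_frame.coords
        r = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(pmap.matrix, contact_function(r), atol=1e-12)

    def test_diagonal_is_f_zero(self, reduced_frame):
        pmap = probability_map(_FrameEnsemble([reduced_frame]))
        assert np.allclose(np.diag(pmap.matrix), contact_function(0.0))

    def test_linearity_over_frames(self, rng):
        frames = [Structure3D(rng.normal(scale=2, size=(12, 3)), UNIT_REDUCED)
                  for _ in range(4)]
        full = probability_map(_FrameEnsemble(frames)).matrix
        avg = np.mean([probability_map(_FrameEnsemble([f])).matrix
                       for f in frames], axis=0)
        assert np.allclose(full, avg, atol=1e-12)

    def test_nm_units_rejected(self, rng):
        frames = [Structure3D(rng.normal(size=(12, 3)), UNIT_NM)]
        with pytest.raises(InvalidArgumentError):
            probability_map(_FrameEnsemble(frames, units=UNIT_NM))


class TestCutoffMap:
    def _pair_ensemble(self, distance, n=5):
        frames = []
        for _ in range(n):
            coords = np.array([[0.0, 0, 0], [distance, 0.0, 0.0]])
            frames.append(Structure3D(coords, UNIT_NM))
        return TracedEnsemble(structures=frames, resolution=50_000)

    def test_always_close_pair_is_one(self):
        cmap = cutoff_map(self._pair_ensemble(100.0))
        assert cmap.matrix[0, 1] == 1.0

    def test_always_far_pair_is_zero(self):
        cmap = cutoff_map(self._pair_ensemble(400.0))
        assert cmap.matrix[0, 1] == 0.0

    def test_denominators_exclude_missing(self):
        # 5 structures; locus 1 missing in 2 of them; contact in 2 of the
        # 3 co-resolved -> 2/3
        frames = []
        for k in range(5):
            coords = np.array([[0.0, 0, 0], [100.0 if k < 2 else 500.0, 0, 0]])
            if k >= 3:
                coords[1] = np.nan
            frames.append(Structure3D(coords, UNIT_NM))
        cmap = cutoff_map(TracedEnsemble(structures=frames, resolution=50_000))
        assert cmap.matrix[0, 1] == pytest.approx(2.0 / 3.0)

    def test_never_coresolved_pair_is_nan(self):
        frames = []
        for k in range(3):
            coords = np.zeros((2, 3))
            coords[k % 2] = np.nan
            frames.append(Structure3D(coords, UNIT_NM))
        cmap = cutoff_map(TracedEnsemble(structures=frames, resolution=50_000))
        assert np.isnan(cmap.matrix[0, 1])

    def test_unit_consistency_nm_vs_reduced(self, rng):
        structures = [Structure3D(rng.normal(scale=400, size=(10, 3)), UNIT_NM)
                      for _ in range(6)]
        ens_nm = TracedEnsemble(structures=structures, resolution=50_000)
        ens_red = convert_units(ens_nm)
        m_nm = cutoff_map(ens_nm, cutoff=330.0).matrix
        m_red = cutoff_map(ens_red, cutoff=2.0).matrix
        assert np.allclose(m_nm, m_red, equal_nan=True)


class TestPearsonByDistance:
    def test_self_comparison_is_one(self, rng):
        m = rng.random((20, 20))
        m = (m + m.T) / 2
        cmap = ContactMap(matrix=m, kind="frequency")
        pbd = pearson_by_distance(cmap, cmap)
        defined = pbd["pearson_r"].dropna()
        assert np.allclose(defined, 1.0)

    def test_shuffled_diagonals_decorrelate(self, rng):
        n = 60
        m = rng.random((n, n))
        m = (m + m.T) / 2
        shuffled = m.copy()
        for d in range(1, n):
            idx = np.arange(n - d)
            perm = rng.permutation(idx)
            shuffled[idx, idx + d] = m[perm, perm + d]
            shuffled[idx + d, idx] = shuffled[idx, idx + d]
        pbd = pearson_by_distance(ContactMap(matrix=m, kind="frequency"),
                                  ContactMap(matrix=shuffled, kind="frequency"))
        rs = pbd["pearson_r"].dropna()
        long_diagonals = rs[pbd["n_pairs"] >= 20]
        # permutation null: sd ~ 1/sqrt(n_pairs)
        assert np.abs(long_diagonals.mean()) < 0.15

    def test_constant_diagonal_undefined(self):
        m = np.full((10, 10), 0.5)
        pbd = pearson_by_distance(ContactMap(matrix=m, kind="frequency"),
                                  ContactMap(matrix=m, kind="frequency"))
        assert pbd["pearson_r"].isna().all()

    def test_shape_mismatch_rejected(self):
        a = ContactMap(matrix=np.eye(5), kind="frequency")
        b = ContactMap(matrix=np.eye(6), kind="frequency")
        with pytest.raises(InvalidArgumentError):
            pearson_by_distance(a, b)


def checkerboard_map(n=20, hi=0.9, lo=0.1):
    m = np.full((n, n), lo)
    half = n // 2
    m[:half, :half] = hi
    m[half:, half:] = hi
    np.fill_diagonal(m, 1.0)
    return ContactMap(matrix=m, kind="frequency")


class TestABAnnotation:
    def test_two_block_checkerboard_split_exactly(self):
        profile = ab_annotation(checkerboard_map())
        signs = np.sign(profile.score)
        assert len(set(signs[:10])) == 1
        assert len(set(signs[10:])) == 1
        assert signs[0] != signs[10]

    def test_scale_invariance(self):
        base = checkerboard_map()
        scaled = ContactMap(matrix=0.5 * base.matrix, kind="frequency")
        a = ab_annotation(base, reference_a=np.r_[np.ones(10), np.zeros(10)])
        b = ab_annotation(scaled, reference_a=np.r_[np.ones(10), np.zeros(10)])
        assert np.allclose(a.score, b.score, atol=1e-10)

    def test_zero_variance_map_degenerate(self):
        m = np.full((12, 12), 0.3)
        with pytest.raises(UndefinedResultError):
            ab_annotation(ContactMap(matrix=m, kind="frequency"))

    def test_phase_separated_run_recovers_types(self, phase_separated_ensemble):
        labels, ens = phase_separated_ensemble
        pmap = probability_map(ens)
        ref = (labels == "A1").astype(float)
        profile = ab_annotation(pmap, reference_a=ref)
        called_a = profile.score > 0
        agreement = np.mean(called_a == (labels == "A1"))
        assert agreement >= 0.9


class TestAnnotationCorrelation:
    def test_self_is_one(self, rng):
        p = CompartmentProfile(score=rng.normal(size=50))
        assert annotation_correlation(p, p) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        p = CompartmentProfile(score=rng.normal(size=50))
        q = CompartmentProfile(score=-p.score)
        assert annotation_correlation(p, q) == pytest.approx(-1.0)

    def test_independent_profiles_near_zero(self, rng):
        r = [annotation_correlation(
            CompartmentProfile(score=rng.normal(size=1000)),
            CompartmentProfile(score=rng.normal(size=1000)))
            for _ in range(20)]
        assert np.mean(np.abs(r) < 0.1) >= 0.95
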