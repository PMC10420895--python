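import numpy as np
import pytest

from lacto2d import corr2d
from lacto2d.dataio import SpectralDataset, Spectrum
from lacto2d.exceptions import GridError, Lacto2dError


def _ds(rows, grid=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    grid = np.arange(400.0, 400.0 + 2 * rows.shape[1], 2.0) if grid is None else grid
    return SpectralDataset.from_spectra(
        [Spectrum(grid, r, sample_id=f"s{i}") for i, r in enumerate(rows)]
    )


def _spec(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = np.arange(400.0, 400.0 + 2 * values.size, 2.0) if grid is None else grid
    return Spectrum(grid, values)


class TestReference:
    def test_mean_of_one_is_itself(self):
        ds = _ds([[0.1, 0.2, 0.3]])
        np.testing.assert_allclose(
            corr2d.reference_spectrum(ds).absorbance, [0.1, 0.2, 0.3]
        )

    def test_mean_of_x_and_3x(self):
        x = np.array([0.1, 0.2, 0.3])
        np.testing.assert_allclose(
            corr2d.reference_spectrum(_ds([x, 3 * x])).absorbance, 2 * x
        )

    def test_matches_loop_oracle(self, rng):
        rows = rng.normal(size=(27, 8))
        acc = np.zeros(8)
        for r in rows:
            acc += r
        np.testing.assert_allclose(
            corr2d.reference_spectrum(_ds(rows)).absorbance, acc / 27, atol=1e-12
        )


class TestDynamic:
    def test_zero_when_equal_and_identity_on_zero_ref(self):
        s = _spec([0.4, 0.5, 0.6, 0.7])
        np.testing.assert_allclose(
            corr2d.dynamic_spectrum(s, s).absorbance, 0.0, atol=0
        )
        zero = _spec([0, 0, 0, 0])
        np.testing.assert_allclose(
            corr2d.dynamic_spectrum(s, zero).absorbance, s.absorbance
        )

    def test_hand_computed_difference(self):
        s = _spec([1.0, 2.0, 4.0, 8.0])
        r = _spec([0.5, 1.0, 1.0, 3.0])
        np.testing.assert_allclose(
            corr2d.dynamic_spectrum(s, r).absorbance, [0.5, 1.0, 3.0, 5.0]
        )

    def test_grid_mismatch(self):
        with pytest.raises(GridError):
            corr2d.dynamic_spectrum(_spec([1, 2, 3]), _spec([1, 2]))


class TestSynchronousSingle:
    def test_zero_matrix_at_reference(self):
        s = _spec([0.3, 0.6, 0.9])
        m = corr2d.synchronous_single(s, s)
        assert np.all(m.values == 0)

    def test_outer_product_example(self):
        s = _spec([1.0, 2.0])
        ref = _spec([0.0, 0.0])
        np.testing.assert_allclose(
            corr2d.synchronous_single(s, ref).values, [[1, 2], [2, 4]]
        )

    def test_matches_double_loop_oracle(self, rng):
        s = _spec(rng.normal(size=10))
        ref = _spec(rng.normal(size=10))
        m = corr2d.synchronous_single(s, ref).values
        d = s.absorbance - ref.absorbance
        oracle = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                oracle[i, j] = d[i] * d[j]
        np.testing.assert_allclose(m, oracle, rtol=1e-12)
        np.testing.assert_allclose(m, m.T, rtol=1e-12)
        assert np.all(np.diag(m) >= 0)


class TestSynchronousEnsemble:
    def test_zero_when_group_equals_reference(self):
        x = np.array([0.2, 0.4, 0.6])
        m = corr2d.synchronous_ensemble(_ds([x, x]), _spec(x))
        assert np.all(m.values == 0)

    def test_orthogonal_pair_identity(self):
        ref = _spec([0.0, 0.0])
        m = corr2d.synchronous_ensemble(_ds([[1.0, 0.0], [0.0, 1.0]]), ref)
        np.testing.assert_allclose(m.values, np.eye(2))

    def test_matches_triple_loop_oracle(self, rng):
        rows = rng.normal(size=(5, 8))
        ref = _spec(rng.normal(size=8))
        m = corr2d.synchronous_ensemble(_ds(rows), ref).values
        d = rows - ref.absorbance
        oracle = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                for k in range(5):
                    oracle[i, j] += d[k, i] * d[k, j]
        oracle /= 4
        np.testing.assert_allclose(m, oracle, rtol=1e-10, atol=1e-12)

    def test_positive_semidefinite(self, rng):
        rows = rng.normal(size=(6, 12))
        ref = _spec(rng.normal(size=12))
        m = corr2d.synchronous_ensemble(_ds(rows), ref).values
        eig = np.linalg.eigvalsh(m)
        assert eig.min() >= -1e-10 * max(eig.max(), 1.0)

    def test_single_vs_ensemble_normalization(self, rng):
        """m identical copies give ensemble = m/(m-1) * per-sample map."""
        x = rng.normal(size=6)
        ref = _spec(rng.normal(size=6))
        single = corr2d.synchronous_single(_spec(x), ref).values
        for m in (2, 4):
            ens = corr2d.synchronous_ensemble(_ds([x] * m), ref).values
            np.testing.assert_allclose(ens, single * m / (m - 1), rtol=1e-10)

    def test_needs_two_spectra(self):
        with pytest.raises(Lacto2dError):
            corr2d.synchronous_ensemble(_ds([[1.0, 2.0]]), _spec([0.0, 0.0]))


class TestAsynchronous:
    def test_identical_dynamic_spectra_give_zero(self):
        x = np.array([0.5, 0.1, 0.9, 0.3])
        m = corr2d.asynchronous_ensemble(_ds([x, x, x]), _spec(np.zeros(4)))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_antisymmetric_zero_diagonal(self, rng):
        rows = rng.normal(size=(5, 7))
        m = corr2d.asynchronous_ensemble(_ds(rows), _spec(rng.normal(size=7))).values
        np.testing.assert_allclose(m, -m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        rows = rng.normal(size=(4, 6))
        ref = rng.normal(size=6)
        m = corr2d.asynchronous_ensemble(_ds(rows), _spec(ref)).values
        d = rows - ref
        n = np.zeros((4, 4))
        for j in range(4):
            for k in range(4):
                if j != k:
                    n[j, k] = 1.0 / (np.pi * (k - j))
        oracle = np.zeros((6, 6))
        for i in range(6):
            for l in range(6):
                for j in range(4):
                    for k in range(4):
                        oracle[i, l] += d[j, i] * n[j, k] * d[k, l]
        oracle /= 3
        np.testing.assert_allclose(m, oracle, atol=1e-12)

    def test_needs_three(self):
        with pytest.raises(Lacto2dError):
            corr2d.asynchronous_ensemble(
                _ds([[1.0, 0.0], [0.0, 1.0]]), _spec([0.0, 0.0])
            )


class TestAutocorrAndPeaks:
    def test_diagonal_extraction(self):
        m = corr2d.SyncCorrMatrix(np.array([400.0, 402.0]), np.array([[1.0, 2.0], [2.0, 4.0]]))
        np.testing.assert_allclose(corr2d.autocorrelation(m).values, [1.0, 4.0])

    def test_diagonal_is_squared_dynamic(self, rng):
        s = _spec(rng.normal(size=9))
        ref = _spec(rng.normal(size=9))
        auto = corr2d.autocorrelation(corr2d.synchronous_single(s, ref)).values
        np.testing.assert_allclose(auto, (s.absorbance - ref.absorbance) ** 2)

    def test_peak_value_symmetry_and_exact_lookup(self, rng):
        grid = np.arange(1400.0, 2000.0, 2.0)
        rows = rng.normal(size=(4, grid.size))
        m = corr2d.synchronous_ensemble(_ds(rows, grid), _spec(rng.normal(size=grid.size), grid))
        assert corr2d.peak_value(m, 1450, 1940) == corr2d.peak_value(m, 1940, 1450)
        i = int((1450 - 1400) // 2)
        j = int((1940 - 1400) // 2)
        assert corr2d.peak_value(m, 1450, 1940) == m.values[i, j]

    def test_nearest_grid_lookup_ties_toward_lower(self):
        grid = np.arange(1400.0, 1500.0, 2.0)
        assert corr2d.nearest_index(grid, 1451.0) == corr2d.nearest_index(grid, 1450.0)
        assert corr2d.nearest_index(grid, 1451.2) == corr2d.nearest_index(grid, 1452.0)

    def test_out_of_range_rejected(self):
        grid = np.arange(1400.0, 1500.0, 2.0)
        m = corr2d.SyncCorrMatrix(grid, np.zeros((grid.size, grid.size)))
        with pytest.raises(Lacto2dError):
            corr2d.peak_value(m, 1300.0, 1450.0)


def test_spoilage_peaks_grow_with_storage(default_dataset, fresh_reference):
    """Autocorrelation peaks at the spoilage wavelengths grow day over day.

    The reference sits inside the fresh window (mean of label-A spectra), so
    the day-0 map is not exactly zero; growth is strictly monotone from day 1
    onward and the day-6 intensity dwarfs day 0.
    """
    meta = default_dataset.metadata
    for nm in (1194, 1450, 1790, 1940):
        per_day = []
        for day in range(7):
            grp = default_dataset.subset((meta["storage_time"] == 24.0 * day).to_numpy())
            mat = corr2d.synchronous_ensemble(grp, fresh_reference)
            per_day.append(corr2d.peak_value(mat, nm, nm))
        assert all(b > a for a, b in zip(per_day[1:], per_day[2:])), nm
        assert per_day[6] > 50 * per_day[0]


def test_day6_peak_enhancement_spans_large_dynamic_range(default_dataset, fresh_reference):
    """Day-6 autocorrelation at 1450 nm exceeds the day-0 value by orders of magnitude."""
    meta = default_dataset.metadata
    day0 = default_dataset.subset((meta["storage_time"] == 0.0).to_numpy())
    day6 = default_dataset.subset((meta["storage_time"] == 144.0).to_numpy())
    p0 = np.mean(
        [corr2d.peak_value(corr2d.synchronous_single(s, fresh_reference), 1450, 1450)
         for s in day0]
    )
    p6 = np.mean(
        [corr2d.peak_value(corr2d.synchronous_single(s, fresh_reference), 1450, 1450)
         for s in day6]
    )
    assert p6 / p0 > 1e2
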