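"""Snapshot indicator tests: moments, Moran's I, SDR, summaries and trends."""

import numpy as np
import pytest

from sewscape import (
    gradient_trend,
    morans_i,
    sews_summary,
    spatial_skewness,
    spatial_variance,
    spectral_density_ratio,
)
from sewscape.grid import Grid, SnapshotSeries
from sewscape.metrics import UndefinedMetricError
from sewscape.synthetic import checkerboard, gaussian_blob, two_block


def morans_i_bruteforce(values, mask=None):
    """Independent O(N^2) Moran's I with rook weights, non-periodic."""
    nr, nc = values.shape
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    cells = [(r, c) for r in range(nr) for c in range(nc) if not mask[r, c]]
    vals = np.array([values[r, c] for r, c in cells], dtype=float)
    z = vals - vals.mean()
    zmap = {rc: z[i] for i, rc in enumerate(cells)}
    num = w = 0.0
    for r, c in cells:
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nb = (r + dr, c + dc)
            if nb in zmap:
                num += zmap[(r, c)] * zmap[nb]
                w += 1.0
    return (len(cells) / w) * num / (z**2).sum()


class TestMoments:
    def test_constant_grid_zero_variance(self):
        assert spatial_variance(Grid(np.full((4, 4), 3.0))) == 0.0

    def test_hand_computed_variance(self):
        g = Grid(np.array([[0.0, 1.0], [1.0, 1.0]]))
        assert g.mean() == 0.75
        assert spatial_variance(g) == pytest.approx(0.1875)

    def test_symmetric_values_zero_skewness(self):
        g = Grid(np.array([[-1.0, 0.0, 1.0]] * 3))
        assert spatial_skewness(g) == pytest.approx(0.0, abs=1e-12)

    def test_skewness_undefined_on_constant(self):
        with pytest.raises(UndefinedMetricError):
            spatial_skewness(Grid(np.ones((3, 3))))

    def test_mask_excludes_cells(self):
        vals = np.array([[0.0, 1.0], [1.0, 99.0]])
        mask = np.array([[False, False], [False, True]])
        g = Grid(vals, mask=mask)
        assert spatial_variance(g) == pytest.approx(np.var([0.0, 1.0, 1.0]))


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        assert morans_i(checkerboard(8)) == pytest.approx(-1.0, abs=1e-12)

    def test_two_block_against_bruteforce(self):
        g = two_block(4)
        expected = morans_i_bruteforce(g.values)
        assert morans_i(g) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2.0 / 3.0)  # hand-summed weights

    def test_random_grids_match_bruteforce(self, rng):
        for _ in range(5):
            vals = rng.random((7, 9))
            mask = rng.random((7, 9)) < 0.15
            got = morans_i(Grid(vals, mask=mask))
            assert got == pytest.approx(morans_i_bruteforce(vals, mask), abs=1e-10)

    def test_permutation_null_mean(self, rng):
        """Under spatial randomness E[I] = -1/(N-1)."""
        vals = rng.random((12, 12))
        n = vals.size
        sims = []
        for _ in range(400):
            sims.append(morans_i(Grid(rng.permutation(vals.ravel()).reshape(12, 12))))
        assert np.mean(sims) == pytest.approx(-1.0 / (n - 1), abs=6e-3)

    def test_queen_and_periodic_variants_run(self):
        g = two_block(8)
        assert -1.01 <= morans_i(g, neighbourhood="queen") <= 1.01
        # periodic two-block: wrap-around boundary pairs oppose
        assert morans_i(g, periodic=True) < morans_i(g, periodic=False)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            morans_i(Grid(np.ones((4, 4))))


class TestSDR:
    def test_white_noise_near_one(self, rng):
        vals = [
            spectral_density_ratio(Grid(rng.standard_normal((64, 64))))
            for _ in range(50)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_checkerboard_all_power_at_nyquist(self):
        assert spectral_density_ratio(checkerboard(16)) == 0.0

    def test_broad_blob_dominated_by_low_frequencies(self):
        assert spectral_density_ratio(gaussian_blob(64)) > 100.0

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            spectral_density_ratio(Grid(np.eye(4)))

    def test_masked_cells_need_explicit_fill(self, rng):
        vals = rng.standard_normal((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True
        g = Grid(vals, mask=mask)
        with pytest.raises(ValueError, match="fill_masked"):
            spectral_density_ratio(g)
        assert np.isfinite(spectral_density_ratio(g, fill_masked=True))


class TestInvariances:
    def test_translation_invariance(self, rng):
        vals = rng.random((16, 16))
        for metric in (spatial_variance, spatial_skewness, morans_i,
                       spectral_density_ratio):
            a = metric(Grid(vals))
            b = metric(Grid(vals + 11.0))
            assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_permutation_changes_only_spatial_metrics(self, rng):
        vals = np.sort(rng.random((16, 16)).ravel()).reshape(16, 16)  # structured
        perm = rng.permutation(vals.ravel()).reshape(16, 16)
        assert spatial_variance(Grid(perm)) == pytest.approx(
            spatial_variance(Grid(vals)), abs=1e-14
        )
        assert spatial_skewness(Grid(perm)) == pytest.approx(
            spatial_skewness(Grid(vals)), abs=1e-10
        )
        assert morans_i(Grid(perm)) != pytest.approx(morans_i(Grid(vals)), abs=1e-3)


class TestSummaryAndTrend:
    def test_constant_grid_reports_missing(self):
        res = sews_summary(Grid(np.full((8, 8), 2.0)))
        assert res.mean_cover == 2.0
        assert res.spatial_variance == 0.0
        assert res.spatial_skewness is None
        assert set(res.missing) == {"spatial_skewness", "morans_i", "sdr"}

    def test_binary_grid_matches_bernoulli(self, rng):
        vals = (rng.random((16, 16)) < 0.3).astype(float)
        res = sews_summary(Grid(vals, kind="binary"))
        m = res.mean_cover
        assert res.spatial_variance == pytest.approx(m * (1 - m), abs=1e-14)

    def test_monotone_metric_gives_unit_tau(self, rng):
        grids = [Grid(rng.standard_normal((8, 8)) * (i + 1)) for i in range(5)]
        series = SnapshotSeries([1.0, 2.0, 3.0, 4.0, 5.0], grids)
        tau, p, direction = gradient_trend(series, "spatial_variance")
        assert tau == pytest.approx(1.0)
        assert direction == "increasing"

    def test_too_few_snapshots_rejected(self, rng):
        series = SnapshotSeries([1.0, 2.0], [Grid(rng.random((8, 8)))] * 2)
        with pytest.raises(ValueError):
            gradient_trend(series, "spatial_variance")

    def test_simulator_gradient_trends(self, gradient_series_default):
        """Indicator trends along the grazing gradient, three seeds.

        Variance and Moran's I rise toward the fold.  The spectral density
        ratio (low:high power) rises too: the spatial spectrum reddens as
        the slowest mode softens, concentrating power at low frequencies.
        """
        for seed, series in gradient_series_default.items():
            tau_var, _, _ = gradient_trend(series, "spatial_variance")
            tau_moran, _, _ = gradient_trend(series, "morans_i")
            tau_sdr, _, _ = gradient_trend(series, "sdr")
            assert tau_var > 0, f"variance trend failed for seed {seed}"
            assert tau_moran > 0, f"Moran trend failed for seed {seed}"
            assert tau_sdr > 0, f"SDR reddening trend failed for seed {seed}"
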