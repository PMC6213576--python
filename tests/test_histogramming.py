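"""Voxel grids, smoothing, threshold masks and marginal histograms."""

import numpy as np
import pytest

from tofprofile.geometry import UBMatrix
from tofprofile.histogramming import (
    EmptyGridError,
    EmptyMaskError,
    angular_histogram,
    build_grid,
    smooth_grid,
    threshold_mask,
    tof_histogram,
)


@pytest.fixture()
def ub():
    return UBMatrix(np.eye(3) * 0.2 / (2 * np.pi))


def make_grid(ub, events_frac, peak=(5, 3, 2), eta=0.25, n=9):
    events_q = 2 * np.pi * (np.asarray(peak) + np.asarray(events_frac)) @ ub.matrix.T
    return build_grid(events_q, peak, ub, eta=eta, voxels_per_side=n)


class TestBuildGrid:
    def test_single_event_at_center(self, ub):
        g = make_grid(ub, [[0.0, 0.0, 0.0]])
        assert g.counts.sum() == 1
        assert g.counts[g.center_index] == 1

    def test_counts_match_bruteforce_box_filter(self, ub, rng):
        frac = rng.uniform(-0.4, 0.4, size=(5000, 3))
        g = make_grid(ub, frac, eta=0.25, n=15)
        inbox = np.all(np.abs(frac) <= 0.25, axis=1)
        assert g.counts.sum() == inbox.sum()

    def test_empty_box_flagged(self, ub):
        with pytest.raises(EmptyGridError):
            make_grid(ub, [[0.4, 0.4, 0.4]])  # outside eta=0.25

    def test_eta_validation(self, ub):
        with pytest.raises(ValueError):
            make_grid(ub, [[0, 0, 0]], eta=0.05)
        with pytest.raises(ValueError):
            make_grid(ub, [[0, 0, 0]], n=10)  # even

    def test_axes_span_box(self, ub):
        g = make_grid(ub, [[0.0, 0.0, 0.0]], peak=(5, 3, 2), eta=0.25, n=9)
        ax = g.frac_axes
        assert np.isclose(ax[0][0], 5 - 0.25 + 0.5 / 9 * 0.5)
        assert np.isclose(ax[2][-1], 2 + 0.25 - 0.5 / 9 * 0.5)
        assert np.isclose(ax[1][(9 - 1) // 2], 3.0)


class TestSmoothing:
    def test_constant_grid_unchanged(self, ub):
        g = make_grid(ub, np.zeros((1, 3)), n=5)
        g.counts[:] = 3.0
        assert np.allclose(smooth_grid(g), 3.0)

    def test_central_count_spreads_to_one_27th(self, ub):
        g = make_grid(ub, np.zeros((1, 3)), n=5)
        sm = smooth_grid(g)
        assert np.isclose(sm[2, 2, 2], 1 / 27)
        assert np.isclose(sm[1, 2, 2], 1 / 27)
        assert sm[0, 0, 0] == 0.0

    def test_matches_naive_triple_loop(self, ub, rng):
        g = make_grid(ub, np.zeros((1, 3)), n=7)
        g.counts[:] = rng.poisson(2.0, size=(7, 7, 7)).astype(float)
        sm = smooth_grid(g)
        n = 7
        for _ in range(30):
            i, j, k = rng.integers(0, n, size=3)
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        a, b, c = i + di, j + dj, k + dk
                        if 0 <= a < n and 0 <= b < n and 0 <= c < n:
                            vals.append(g.counts[a, b, c])
            assert np.isclose(sm[i, j, k], np.mean(vals))

    def test_linearity(self, ub, rng):
        g1 = make_grid(ub, np.zeros((1, 3)), n=5)
        g1.counts[:] = rng.poisson(3.0, size=(5, 5, 5)).astype(float)
        g2 = make_grid(ub, np.zeros((1, 3)), n=5)
        g2.counts[:] = rng.poisson(3.0, size=(5, 5, 5)).astype(float)
        lhs = smooth_grid(2.0 * g1.counts + g2.counts)
        rhs = 2.0 * smooth_grid(g1.counts) + smooth_grid(g2.counts)
        assert np.allclose(lhs, rhs)


class TestThresholdMask:
    def test_level_zero_keeps_everything_positive(self):
        sm = np.ones((5, 5, 5))
        mask = threshold_mask(sm, 0.0)
        assert mask.all()

    def test_level_above_max_is_empty(self):
        sm = np.ones((5, 5, 5))
        with pytest.raises(EmptyMaskError):
            threshold_mask(sm, 2.0)

    def test_disjoint_blob_nearest_center_survives(self):
        sm = np.zeros((9, 9, 9))
        sm[3:6, 3:6, 3:6] = 1.0   # central blob
        sm[0, 0, 0] = 5.0         # bright far corner
        mask = threshold_mask(sm, 0.5)
        assert mask[4, 4, 4] and not mask[0, 0, 0]

    def test_matches_connected_component_oracle(self, rng):
        # BFS flood fill from the center voxel with 26-connectivity
        sm = (rng.random((7, 7, 7)) > 0.7).astype(float)
        sm[3, 3, 3] = 1.0
        mask = threshold_mask(sm, 0.5, center_index=(3, 3, 3))
        seen = {(3, 3, 3)}
        queue = [(3, 3, 3)]
        while queue:
            i, j, k = queue.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        a, b, c = i + di, j + dj, k + dk
                        if (0 <= a < 7 and 0 <= b < 7 and 0 <= c < 7
                                and (a, b, c) not in seen and sm[a, b, c] > 0.5):
                            seen.add((a, b, c))
                            queue.append((a, b, c))
        oracle = np.zeros((7, 7, 7), dtype=bool)
        for idx in seen:
            oracle[idx] = True
        assert np.array_equal(mask, oracle)


class TestMarginals:
    def test_tof_counts_conserved(self, ub, rng):
        frac = rng.uniform(-0.25, 0.25, size=(2000, 3))
        g = make_grid(ub, frac, n=15)
        centers, counts = tof_histogram(g, None, flight_path=30.9)
        assert counts.sum() == g.counts.sum()
        mask = g.counts > 0
        _, masked_counts = tof_histogram(g, mask, flight_path=30.9)
        assert masked_counts.sum() == g.counts[mask].sum()

    def test_tof_matches_naive_binning_oracle(self, ub, rng):
        frac = rng.uniform(-0.25, 0.25, size=(500, 3))
        g = make_grid(ub, frac, n=9)
        centers, counts = tof_histogram(g, None, flight_path=30.9, n_bins=12)
        tof = g.voxel_tof(30.9)
        lo, hi = tof.min(), tof.max()
        edges = np.linspace(lo, hi, 13)
        oracle = np.zeros(12)
        for idx in np.ndindex(g.counts.shape):
            b = min(np.searchsorted(edges, tof[idx], side="right") - 1, 11)
            oracle[max(b, 0)] += g.counts[idx]
        assert np.allclose(counts, oracle)

    def test_angular_totals_conserved(self, ub, rng):
        frac = rng.uniform(-0.25, 0.25, size=(2000, 3))
        g = make_grid(ub, frac, n=15)
        _, _, hist, fp, cover = angular_histogram(g, None, n_phi=20, n_two_theta=20)
        assert hist.sum() == g.counts.sum()
        assert cover.sum() == g.counts.size

    def test_radial_displacement_same_angular_cell(self, ub):
        # two events at the same direction, different |q|, land in one cell
        peak = (5, 3, 2)
        q0 = ub.hkl_to_q(np.array(peak, dtype=float))
        ev = np.vstack([q0 * 0.99, q0 * 1.01])
        g = build_grid(ev, peak, ub, eta=0.25, voxels_per_side=15)
        _, _, hist, _, _ = angular_histogram(g, None, n_phi=15, n_two_theta=15)
        assert (hist > 0).sum() == 1
        assert hist.max() == 2

    def test_masked_empty_grid_raises(self, ub):
        g = make_grid(ub, np.zeros((1, 3)), n=5)
        g.counts[:] = 0
        with pytest.raises(EmptyGridError):
            tof_histogram(g, None, 30.9)
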