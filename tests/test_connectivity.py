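"""Low-order, high-order, and cross-band connectivity construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegfc import (
    BandSpec,
    assemble_supra,
    cross_band_global,
    cross_band_lofc,
    hofc,
    lofc,
    plv,
    plv_matrix,
)
from eegfc.connectivity import ConnectivityMatrix, DegenerateEdgeWarning
from eegfc.spectral import BandPhaseTensor

from conftest import random_symmetric_plv
from oracles import hofc_brute

DELTA = BandSpec("delta", 1, 4)
ALPHA = BandSpec("alpha", 8, 13)


def tensor_from_phases(phases, band=ALPHA, fs=250.0, labels=None):
    phases = np.asarray(phases, dtype=float)
    labels = labels or [f"ch{i}" for i in range(phases.shape[0])]
    return BandPhaseTensor(
        band=band, fs=fs, channel_labels=labels, phases=phases,
        valid_range=(0, phases.shape[1]),
    )


class TestPLV:
    def test_identical_phases(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 1000)
        assert plv(ph, ph) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 1000)
        assert plv(ph, ph - np.pi / 3) == pytest.approx(1.0, abs=1e-12)

    def test_balanced_antipodal_phases_cancel(self):
        u = np.zeros(400)
        v = -np.tile([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], 100)
        assert plv(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(10), np.zeros(11))
        with pytest.raises(ValueError):
            plv(np.zeros(1), np.zeros(1))

    @settings(max_examples=50, deadline=None)
    @given(
        offset=st.floats(-10, 10, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_global_phase_shift_invariance(self, offset, seed):
        r = np.random.default_rng(seed)
        u = r.uniform(-np.pi, np.pi, 200)
        v = r.uniform(-np.pi, np.pi, 200)
        assert plv(u + offset, v + offset) == pytest.approx(plv(u, v), abs=1e-10)


class TestLOFC:
    def test_shared_phase_series_gives_all_ones(self, rng):
        ph = np.tile(rng.uniform(-np.pi, np.pi, 500), (4, 1))
        W = lofc(tensor_from_phases(ph)).W
        assert np.allclose(W, 1.0)

    def test_independent_phases_near_zero(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (8, 100_000))
        W = lofc(tensor_from_phases(ph)).W
        off = W[~np.eye(8, dtype=bool)]
        assert off.max() < 0.02  # >5 sigma above the sqrt(pi/4N) null mean

    def test_channel_permutation_equivariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (5, 2000))
        W = lofc(tensor_from_phases(ph)).W
        perm = [3, 1, 4, 0, 2]
        Wp = lofc(tensor_from_phases(ph[perm])).W
        assert np.allclose(Wp, W[np.ix_(perm, perm)])

    def test_matrix_agrees_with_pairwise_plv(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (5, 500))
        W = plv_matrix(ph)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert W[i, j] == pytest.approx(plv(ph[i], ph[j]), abs=1e-12)
        assert np.allclose(W, W.T)
        assert np.all(W >= 0) and np.all(W <= 1)

    def test_single_channel_rejected(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (1, 100))
        with pytest.raises(ValueError):
            lofc(tensor_from_phases(ph))


class TestHOFC:
    def lofc_of(self, W):
        n = W.shape[0]
        return ConnectivityMatrix(
            order="low", bands=(ALPHA,), node_labels=[f"c{i}" for i in range(n)], W=W
        )

    def test_identical_reduced_columns_give_unit_edge(self):
        # columns 0 and 1 identical after removing rows 0 and 1
        W = random_symmetric_plv(np.random.default_rng(5), 6)
        W[2:, 0] = W[2:, 1]
        W[0, 2:] = W[1, 2:]
        H = hofc(self.lofc_of(W)).W
        assert H[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_constant_matrix_degenerates_to_zero_with_warning(self):
        W = np.full((6, 6), 0.5)
        np.fill_diagonal(W, 1.0)
        with pytest.warns(DegenerateEdgeWarning):
            H = hofc(self.lofc_of(W)).W
        assert np.allclose(H, 0.0)

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for n in range(5, 13):
            W = random_symmetric_plv(rng, n)
            H = hofc(self.lofc_of(W)).W
            Hb = np.array(hofc_brute(W.tolist()))
            assert np.max(np.abs(H - Hb)) < 1e-12
            assert np.allclose(H, H.T)
            assert np.all(np.diag(H) == 0)
            assert np.all(np.abs(H) <= 1)

    def test_small_matrix_rejected(self):
        W = random_symmetric_plv(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match=">= 4"):
            hofc(self.lofc_of(W))


class TestCrossBand:
    def test_relabeled_copy_of_locked_channels_gives_ones(self, rng):
        # channels locked at constant offsets; band b a relabeled copy of a:
        # every (i, j) phase difference is then constant, so every entry is 1
        base = np.cumsum(rng.normal(0.2, 0.1, 2000))
        ph = np.vstack([base, base + 0.5, base - 1.0, base + 2.2])
        ta = tensor_from_phases(ph, band=DELTA)
        tb = tensor_from_phases(ph, band=ALPHA)
        assert np.allclose(cross_band_lofc(ta, tb).W, 1.0)

    def test_same_channel_entries_of_relabeled_copy_are_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (4, 2000))
        W = cross_band_lofc(
            tensor_from_phases(ph, band=DELTA), tensor_from_phases(ph, band=ALPHA)
        ).W
        assert np.allclose(np.diag(W), 1.0)

    def test_independent_random_walk_phases_near_zero(self, rng):
        # drifting independent phases; wider bound than the iid null
        pa = np.cumsum(rng.normal(0, 0.3, (4, 100_000)), axis=1)
        pb = np.cumsum(rng.normal(0, 0.3, (4, 100_000)), axis=1)
        W = cross_band_lofc(
            tensor_from_phases(pa, band=DELTA), tensor_from_phases(pb, band=ALPHA)
        ).W
        assert W.max() < 0.05

    def test_channel_mismatch_rejected(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (3, 100))
        ta = tensor_from_phases(pa, band=DELTA, labels=["a", "b", "c"])
        tb = tensor_from_phases(pa, band=ALPHA, labels=["a", "b", "x"])
        with pytest.raises(ValueError, match="channels"):
            cross_band_lofc(ta, tb)

    def test_same_band_rejected(self, rng):
        pa = rng.uniform(-np.pi, np.pi, (3, 100))
        with pytest.raises(ValueError, match="distinct"):
            cross_band_lofc(tensor_from_phases(pa), tensor_from_phases(pa))

    def test_nm_mode_detects_harmonic_locking(self, rng):
        # phi_b = 4 * phi_a + small jitter: invisible at 1:1, strong at 4:1
        t = np.arange(50_000) / 250.0
        pa = 2 * np.pi * 2.5 * t + np.cumsum(rng.normal(0, 0.05, 50_000))
        pb = 4 * pa + np.cumsum(rng.normal(0, 0.002, 50_000))
        ta = tensor_from_phases(np.vstack([pa, pa[::-1]]), band=DELTA)
        tb = tensor_from_phases(np.vstack([pb, pb[::-1]]), band=ALPHA)
        W_nm = cross_band_lofc(ta, tb, nm_ratio=(4, 1)).W
        W_11 = cross_band_lofc(ta, tb).W
        assert W_nm[0, 0] > 0.8
        assert W_11[0, 0] < 0.3


class TestSupra:
    def build(self, C=8, within_val=1.0, between_val=0.5):
        bands = [BandSpec(n, lo, hi) for n, lo, hi in
                 [("delta", 1, 4), ("theta", 4, 8), ("alpha", 8, 13), ("beta", 13, 30)]]
        labels = [f"ch{i}" for i in range(C)]
        within = [
            ConnectivityMatrix(order="low", bands=(b,), node_labels=labels,
                               W=np.full((C, C), within_val))
            for b in bands
        ]
        rng = np.random.default_rng(1)
        between = []
        for i in range(4):
            for j in range(i + 1, 4):
                between.append(
                    ConnectivityMatrix(
                        order="low", bands=(bands[i], bands[j]), node_labels=labels,
                        W=np.full((C, C), between_val),
                    )
                )
        return bands, within, between

    def test_dimensions_and_symmetry(self):
        _, within, between = self.build()
        S = assemble_supra(within, between)
        assert S.S.shape == (32, 32)  # 4 bands x 8 channels
        assert np.array_equal(S.S, S.S.T)
        assert len(S.supra_labels) == 32

    def test_block_placement_and_pair_means(self):
        _, within, between = self.build(between_val=0.5)
        S = assemble_supra(within, between)
        pairs, overall = cross_band_global(S)
        assert len(pairs) == 6
        assert all(v == pytest.approx(0.5) for v in pairs.values())
        assert overall == pytest.approx(0.5)

    def test_single_perturbed_entry_mean(self):
        _, within, between = self.build(between_val=0.5)
        between[0].W[0, 0] = 0.6
        S = assemble_supra(within, between)
        pairs, _ = cross_band_global(S)
        key = ("delta", "theta")
        assert pairs[key] == pytest.approx((63 * 0.5 + 0.6) / 64)

    def test_missing_block_rejected(self):
        _, within, between = self.build()
        with pytest.raises(ValueError, match="missing"):
            assemble_supra(within, between[:-1])

    def test_global_metric_scales_linearly_in_block_scale(self):
        _, within, between = self.build(between_val=0.4)
        S1 = assemble_supra(within, between)
        _, g1 = cross_band_global(S1)
        for M in between:
            M.W = M.W * 2.5
        S2 = assemble_supra(within, between)
        _, g2 = cross_band_global(S2)
        assert g2 == pytest.approx(2.5 * g1)

    def test_asymmetric_between_block_transpose_placement(self):
        bands, within, between = self.build()
        rng = np.random.default_rng(3)
        between[0].W = rng.uniform(0, 1, (8, 8))
        S = assemble_supra(within, between)
        assert np.array_equal(S.block(0, 1), between[0].W)
        assert np.array_equal(S.block(1, 0), between[0].W.T)
        assert np.array_equal(S.S, S.S.T)
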