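"""Voxel fits: round trips, independent oracles, exclusion rules."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from t2dwi import (
    AcquisitionScheme,
    ComponentBasis,
    SignalVolume,
    attenuation_basis,
    build_exclusion_mask,
    fit_bi_exponential_voxel,
    fit_mono_adc_voxel,
    fit_two_component_voxel,
    fit_volume,
    two_component_signal,
)
from t2dwi.fitting import fit_two_component_table, nnls_two_column


def sf_scan_oracle(signal, scheme, basis, step=1e-4):
    """Exhaustive scan over sf_slow with the optimal si0 at each step."""
    A = attenuation_basis(scheme, basis)
    sfs = np.arange(0.0, 1.0 + step / 2, step)
    m = sfs[:, None] * A[:, 0] + (1 - sfs[:, None]) * A[:, 1]  # model shape per sf
    si0 = np.maximum((m @ signal) / np.einsum("ij,ij->i", m, m), 0.0)
    resid = np.linalg.norm(si0[:, None] * m - signal, axis=1)
    best = np.argmin(resid)
    return si0[best], sfs[best]


class TestTwoComponentFit:
    @pytest.mark.parametrize("sf_true", [0.0, 0.33, 0.67, 1.0])
    def test_noise_free_round_trip(self, scheme, basis, sf_true):
        signal = two_component_signal(100.0, sf_true, basis, scheme)
        si0, sf, rmse, valid = fit_two_component_voxel(signal, scheme, basis)
        assert valid
        assert si0 == pytest.approx(100.0, abs=1e-6)
        assert sf == pytest.approx(sf_true, abs=1e-8)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_scipy_nnls(self, scheme, basis, rng):
        A = attenuation_basis(scheme, basis)
        S = np.abs(rng.normal(50, 30, size=(100, 4)))
        coef, rmse = nnls_two_column(A, S)
        for i in range(len(S)):
            ref, ref_res = scipy_nnls(A, S[i])
            assert np.allclose(coef[i], ref, atol=1e-8)
            assert rmse[i] == pytest.approx(ref_res / 2.0, abs=1e-8)  # rmse = ||r||/sqrt(4)

    def test_agrees_with_exhaustive_sf_scan(self, scheme, basis, rng):
        truth = two_component_signal(
            rng.uniform(50, 150, 100), rng.uniform(0, 1, 100), basis, scheme
        )
        noisy = np.abs(truth + rng.normal(0, 3.0, truth.shape))
        _, sf, _, valid = fit_two_component_table(noisy, scheme, basis)
        assert valid.all()
        for i in range(len(noisy)):
            _, sf_ref = sf_scan_oracle(noisy[i], scheme, basis)
            assert sf[i] == pytest.approx(sf_ref, abs=1e-4)

    def test_constraint_keeps_fraction_in_unit_interval(self, scheme, basis):
        signal = two_component_signal(100.0, 0.0, basis, scheme)
        signal[0] += 500.0  # large positive outlier on one measurement
        _, sf, _, valid = fit_two_component_voxel(signal, scheme, basis)
        assert valid and 0.0 <= sf <= 1.0

    @pytest.mark.parametrize(
        "bad", [np.zeros(4), np.full(4, np.nan), np.array([1.0, np.inf, 1.0, 1.0])]
    )
    def test_degenerate_signal_is_invalid(self, scheme, basis, bad):
        si0, sf, rmse, valid = fit_two_component_voxel(bad, scheme, basis)
        assert not valid
        assert np.isnan(si0) and np.isnan(sf)


def biexp_bisection_oracle(s1, s2, b1, b2, adc_pair, tol=1e-12):
    """Bisection on sf_slow over the signal-ratio equation."""

    def ratio(f):
        es = np.exp(-np.array([b1, b2]) * adc_pair[0] * 1e-3)
        ef = np.exp(-np.array([b1, b2]) * adc_pair[1] * 1e-3)
        m = f * es + (1 - f) * ef
        return m[1] / m[0]

    target = s2 / s1
    lo, hi = 0.0, 1.0
    # ratio is monotone increasing in f (the slow component decays less with b)
    for _ in range(100):
        mid = (lo + hi) / 2
        if ratio(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestBiExponentialFit:
    def test_pure_slow_recovered_exactly(self):
        from t2dwi import bi_exponential_signal

        s = bi_exponential_signal(100.0, 1.0, (0.3, 2.6), [50.0, 700.0])
        si0, sf, valid = fit_bi_exponential_voxel(s[0], s[1], 50.0, 700.0, (0.3, 2.6))
        assert valid and sf == pytest.approx(1.0, abs=1e-12)

    def test_matches_bisection_oracle(self):
        from t2dwi import bi_exponential_signal

        s = bi_exponential_signal(1.0, 0.42, (0.3, 2.6), [50.0, 700.0])
        si0, sf, valid = fit_bi_exponential_voxel(s[0], s[1], 50.0, 700.0, (0.3, 2.6))
        ref = biexp_bisection_oracle(s[0], s[1], 50.0, 700.0, (0.3, 2.6))
        assert sf == pytest.approx(0.42, abs=1e-9)
        assert sf == pytest.approx(ref, abs=1e-9)
        assert si0 == pytest.approx(1.0, rel=1e-9)

    def test_rising_signal_clips_to_boundary(self):
        # a signal rising with b lies beyond even the slowest-decaying
        # component, so the constrained solution saturates at sf_slow = 1
        si0, sf, valid = fit_bi_exponential_voxel(50.0, 60.0, 50.0, 700.0, (0.3, 2.6))
        assert sf == 1.0

    def test_nonpositive_signal_invalid(self):
        _, _, valid = fit_bi_exponential_voxel(0.0, 10.0, 50.0, 700.0, (0.3, 2.6))
        assert not valid


class TestMonoFit:
    def test_equal_signals_give_zero_adc(self):
        _, adc, valid = fit_mono_adc_voxel(80.0, 80.0, 50.0, 700.0)
        assert valid and adc == 0.0

    def test_closed_form_worked_value(self):
        si0, adc, valid = fit_mono_adc_voxel(100.0, 52.205, 50.0, 700.0)
        assert adc == pytest.approx(1.000, abs=1e-4)
        assert si0 == pytest.approx(100.0 * np.exp(50 * adc * 1e-3), rel=1e-9)

    def test_negative_adc_passes_through_for_exclusion(self):
        _, adc, valid = fit_mono_adc_voxel(50.0, 60.0, 50.0, 700.0)
        assert valid and adc < 0

    def test_round_trip_with_forward_model(self):
        from t2dwi import mono_exponential_signal

        s = mono_exponential_signal(90.0, 1.3, [50.0, 700.0])
        _, adc, _ = fit_mono_adc_voxel(s[0], s[1], 50.0, 700.0)
        assert adc == pytest.approx(1.3, rel=1e-12)


def make_volume(data, scheme, box=None, bg=None):
    shape = data.shape[:3]
    if box is None:
        box = np.zeros(shape, bool)
        box[1:-1, 1:-1, :] = True
    if bg is None:
        bg = np.zeros(shape, bool)
        bg[0, :, :] = True
    return SignalVolume(data=data, scheme=scheme, box_mask=box, background_mask=bg)


class TestExclusionRules:
    def build(self, scheme, tissue_value=100.0, bg_value=10.0, shape=(4, 4, 1)):
        data = np.full(shape + (4,), tissue_value)
        vol = make_volume(data, scheme)
        vol.data[vol.background_mask] = bg_value
        return vol

    def test_noise_floor_boundary_equal_excluded_above_kept(self, scheme):
        vol = self.build(scheme)
        vol.data[1, 1, 0, 2] = 30.0  # exactly 3 x floor of 10.0
        vol.data[2, 2, 0, :] = 30.1
        keep, qc = build_exclusion_mask(vol)
        assert qc["noise_floor"] == pytest.approx(10.0)
        assert not keep[1, 1, 0]
        assert keep[2, 2, 0]

    def test_rising_signal_with_b_excluded(self, scheme):
        vol = self.build(scheme)
        i50 = scheme.measurement_index(73.0, 50.0)
        i700 = scheme.measurement_index(73.0, 700.0)
        vol.data[1, 2, 0, i700] = vol.data[1, 2, 0, i50] + 1.0
        keep, qc = build_exclusion_mask(vol)
        assert not keep[1, 2, 0]
        assert qc["n_negative_adc"] == 1

    def test_rising_signal_with_te_excluded(self, scheme):
        vol = self.build(scheme)
        i55 = scheme.measurement_index(55.0, 700.0)
        i73 = scheme.measurement_index(73.0, 700.0)
        vol.data[2, 1, 0, i73] = vol.data[2, 1, 0, i55] + 1.0
        keep, qc = build_exclusion_mask(vol)
        assert not keep[2, 1, 0]
        assert qc["n_negative_t2"] == 1

    def test_empty_background_raises(self, scheme):
        data = np.full((3, 3, 1, 4), 100.0)
        vol = make_volume(data, scheme, bg=np.zeros((3, 3, 1), bool))
        with pytest.raises(ValueError, match="background"):
            build_exclusion_mask(vol)


class TestFitVolume:
    def make_truth_volume(self, scheme, basis, rng, shape=(6, 6, 2)):
        sf = rng.uniform(0.1, 0.9, shape)
        si0 = rng.uniform(80, 120, shape)
        data = two_component_signal(si0.ravel(), sf.ravel(), basis, scheme).reshape(shape + (4,))
        vol = make_volume(data, scheme)
        vol.data[vol.background_mask] = 0.0
        return vol, sf, si0

    def test_noiseless_round_trip_map(self, scheme, basis, rng):
        vol, sf, si0 = self.make_truth_volume(scheme, basis, rng)
        maps = fit_volume(vol, "two_component", basis=basis)
        ok = maps.valid
        assert ok.sum() == vol.box_mask.sum()
        assert np.allclose(maps["sf_slow"][ok], sf[ok], atol=1e-6)
        assert np.allclose(maps["si0"][ok], si0[ok], atol=1e-4)
        assert np.isnan(maps["sf_slow"][~ok]).all()

    def test_voxel_independence_under_permutation(self, scheme, basis, rng):
        S = np.abs(rng.normal(60, 20, size=(50, 4)))
        si0_a, sf_a, _, _ = fit_two_component_table(S, scheme, basis)
        perm = rng.permutation(50)
        si0_b, sf_b, _, _ = fit_two_component_table(S[perm], scheme, basis)
        assert np.allclose(si0_a[perm], si0_b)
        assert np.allclose(sf_a[perm], sf_b)

    def test_qc_counts_match_brute_force(self, scheme, basis, rng):
        vol, _, _ = self.make_truth_volume(scheme, basis, rng, shape=(8, 8, 2))
        vol.data[vol.box_mask] += rng.normal(0, 30, (int(vol.box_mask.sum()), 4))
        vol.data = np.abs(vol.data)
        vol.data[vol.background_mask] = 10.0
        keep, qc = build_exclusion_mask(vol)
        floor = vol.data[vol.background_mask].mean()
        n_excl = 0
        idx = {m: i for i, m in enumerate(vol.scheme.measurements)}
        for x, y, z in zip(*np.nonzero(vol.box_mask)):
            s = vol.data[x, y, z]
            bad = (s <= 3 * floor).any()
            for te in vol.scheme.echo_times:
                bad |= s[idx[(te, 50.0)]] < s[idx[(te, 700.0)]]
            for b in vol.scheme.b_values:
                bad |= s[idx[(55.0, b)]] < s[idx[(73.0, b)]]
            n_excl += bool(bad)
        assert qc["n_excluded"] == n_excl
        assert qc["excluded_fraction"] == pytest.approx(n_excl / vol.box_mask.sum())

    def test_no_fit_exists_for_excluded_voxels(self, scheme, basis, rng):
        vol, _, _ = self.make_truth_volume(scheme, basis, rng)
        vol.data[2, 2, 0, :] = 1.0  # below noise threshold once bg is nonzero
        vol.data[vol.background_mask] = 5.0
        maps = fit_volume(vol, "two_component", basis=basis)
        assert not maps.valid[2, 2, 0]
        assert np.isnan(maps["sf_slow"][2, 2, 0])
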