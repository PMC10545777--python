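import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import operantfp as ofp
from operantfp.fiber import Recording


def _rec(time, signal, iso):
    return Recording(1, np.asarray(time, float), np.asarray(signal, float), np.asarray(iso, float))


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------


class TestReaders:
    def test_csv_toy_file(self, tmp_path, cfg):
        f = tmp_path / "f.csv"
        cols = cfg.fiber.columns
        f.write_text(
            f"{cols['time']},{cols['signal']},{cols['isosbestic']}\n"
            + "".join(f"{i/1000},{0.1+i/1e4},{0.08+i/1e4}\n" for i in range(5))
        )
        raw = ofp.read_fiber_csv(f, cfg)
        assert raw.time.size == raw.signal.size == raw.isosbestic.size == 5

    def test_nan_rows_dropped_with_count(self, tmp_path, cfg):
        t = np.arange(1001) / 1000
        s = np.full(1001, 0.1)
        i = np.full(1001, 0.08)
        s[500] = np.nan
        f = tmp_path / "f.csv"
        ofp.write_fiber_csv(t, s, i, f)
        with pytest.warns(UserWarning, match="1 non-finite"):
            raw = ofp.read_fiber_csv(f, cfg)
        assert raw.time.size == 1000
        assert raw.dropped_rows == 1

    def test_missing_mapped_column_fatal(self, tmp_path, cfg):
        f = tmp_path / "f.csv"
        f.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="missing mapped columns"):
            ofp.read_fiber_csv(f, cfg)

    def test_hdf5_equals_csv_twin(self, tmp_path, cfg):
        truth = ofp.simulate_behavior(ofp.SessionTemplate(periods=(("drug", 30.0),), seed=1))
        t, s, i, _ = ofp.simulate_photometry(truth, ofp.PhotometryTemplate(blocks=((0.0, 10.0),), seed=2))
        ofp.write_fiber_csv(t, s, i, tmp_path / "f.csv")
        ofp.write_fiber_hdf5(t, s, i, tmp_path / "f.h5")
        a = ofp.read_fiber_csv(tmp_path / "f.csv", cfg)
        b = ofp.read_fiber_hdf5(tmp_path / "f.h5", cfg)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.isosbestic, b.isosbestic)
        # and both recover the generated arrays exactly
        assert np.array_equal(a.signal, s)

    def test_hdf5_missing_or_empty_dataset_fatal(self, tmp_path, cfg):
        import h5py

        f = tmp_path / "bad.h5"
        with h5py.File(f, "w") as h:
            h.create_dataset("time", data=np.arange(5.0))
            h.create_dataset("signal", data=np.arange(5.0))
        with pytest.raises(ValueError, match="missing HDF5 dataset"):
            ofp.read_fiber_hdf5(f, cfg)
        with h5py.File(f, "a") as h:
            h.create_dataset("isosbestic", data=np.empty(0))
        with pytest.raises(ValueError, match="empty HDF5 dataset"):
            ofp.read_fiber_hdf5(f, cfg)


# --------------------------------------------------------------------------
# Recording splitting
# --------------------------------------------------------------------------


class TestSplitRecordings:
    def test_uniform_sampling_single_recording(self):
        t = np.arange(10_000) * 0.001
        raw = ofp.RawFiberFile("m", t, np.ones_like(t), np.ones_like(t))
        recs = ofp.split_recordings(raw)
        assert len(recs) == 1 and recs[0].index == 1

    def test_two_blocks_split_with_correct_rate(self):
        t1 = np.arange(10_000) * 0.001
        t2 = 300.0 + np.arange(10_000) * 0.001
        t = np.concatenate([t1, t2])
        raw = ofp.RawFiberFile("m", t, np.ones_like(t), np.ones_like(t))
        recs = ofp.split_recordings(raw, gap_threshold_s=1.0, min_length_s=5.0)
        assert [r.index for r in recs] == [1, 2]
        for r in recs:
            assert r.sampling_rate == pytest.approx(1000.0, rel=1e-6)

    def test_gap_exactly_at_threshold_does_not_split(self):
        t = np.concatenate([np.arange(0, 10, 0.1), 10.9 + np.arange(0, 10, 0.1)])
        raw = ofp.RawFiberFile("m", t, np.ones_like(t), np.ones_like(t))
        assert len(ofp.split_recordings(raw, gap_threshold_s=1.0, min_length_s=5.0)) == 1

    def test_short_segment_discarded_with_warning(self):
        t = np.concatenate([np.arange(0, 10, 0.01), 100.0 + np.arange(0, 1, 0.01)])
        raw = ofp.RawFiberFile("m", t, np.ones_like(t), np.ones_like(t))
        with pytest.warns(UserWarning, match="below minimum length"):
            recs = ofp.split_recordings(raw, gap_threshold_s=1.0, min_length_s=5.0)
        assert len(recs) == 1


# --------------------------------------------------------------------------
# dF/F
# --------------------------------------------------------------------------


class TestComputeDff:
    def test_identical_channels_give_unity_fit_and_zero_values(self):
        x = np.linspace(1.0, 2.0, 50)
        ns = ofp.compute_dff(_rec(np.arange(50.0), x, x))
        a, b = ns.coefficients
        assert a == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ns.values, 0.0, atol=1e-12)

    def test_exact_proportionality(self):
        iso = np.array([1.0, 2.0, 3.0, 4.0])
        ns = ofp.compute_dff(_rec(np.arange(4.0), 2 * iso, iso))
        assert ns.coefficients == (pytest.approx(2.0, abs=1e-12), pytest.approx(0.0, abs=1e-12))
        assert np.allclose(ns.values, 0.0, atol=1e-12)

    def test_recovers_closed_form_ols_with_one_transient(self):
        rng = np.random.default_rng(0)
        iso = rng.uniform(1.0, 2.0, 200)
        sig = 0.9 * iso + 0.05
        sig[90:100] += 0.5  # additive transient on the signal channel only
        ns = ofp.compute_dff(_rec(np.arange(200.0), sig, iso))
        # independent closed-form OLS
        xb, yb = iso.mean(), sig.mean()
        a_hat = np.sum((iso - xb) * (sig - yb)) / np.sum((iso - xb) ** 2)
        b_hat = yb - a_hat * xb
        assert ns.coefficients[0] == pytest.approx(a_hat, abs=1e-6)
        assert ns.coefficients[1] == pytest.approx(b_hat, abs=1e-6)
        off = np.ones(200, bool)
        off[90:100] = False
        assert np.abs(ns.values[off]).max() < 0.05

    def test_zero_variance_isosbestic_fatal(self):
        with pytest.raises(ValueError, match="degenerate control"):
            ofp.compute_dff(_rec(np.arange(4.0), [1, 2, 3, 4], np.ones(4)))

    def test_non_positive_fitted_baseline_fatal(self):
        with pytest.raises(ValueError, match="non-positive"):
            ofp.compute_dff(_rec(np.arange(3.0), [-1.0, -2.0, -3.0], [1.0, 2.0, 3.0]))

    def test_invariant_to_common_positive_scaling(self):
        rng = np.random.default_rng(1)
        iso = rng.uniform(1.0, 2.0, 100)
        sig = 0.8 * iso + 0.1 + rng.normal(0, 0.01, 100)
        v1 = ofp.compute_dff(_rec(np.arange(100.0), sig, iso)).values
        v2 = ofp.compute_dff(_rec(np.arange(100.0), 3.7 * sig, 3.7 * iso)).values
        assert np.allclose(v1, v2, atol=1e-12)

    def test_correction_reduces_shared_artifact_leakage(self):
        rng = np.random.default_rng(2)
        n = 20_000
        t = np.arange(n) / 1000
        base = 0.15 * np.exp(-t / 2000)
        rho = np.exp(-1 / (1000 * 0.5))
        eps = rng.normal(0, 0.002 * np.sqrt(1 - rho**2), n)
        from scipy.signal import lfilter

        artifact = lfilter([1.0], [1.0, -rho], eps)
        sig = base + artifact + rng.normal(0, 0.001, n)
        iso = 0.85 * base + 0.01 + artifact + rng.normal(0, 0.001, n)
        dff = ofp.compute_dff(_rec(t, sig, iso)).values
        r_raw = abs(np.corrcoef(sig, artifact)[0, 1])
        r_dff = abs(np.corrcoef(dff, artifact)[0, 1])
        assert r_dff < r_raw


# --------------------------------------------------------------------------
# Z-difference
# --------------------------------------------------------------------------


class TestComputeZdiff:
    def test_identical_channels_give_zero(self):
        x = np.sin(np.arange(100.0))
        ns = ofp.compute_zdiff(_rec(np.arange(100.0), x, x))
        assert ns.method == "Z"
        assert np.allclose(ns.values, 0.0, atol=1e-12)

    def test_antisymmetry(self):
        x = np.sin(np.arange(100.0)) + 2.0
        ns = ofp.compute_zdiff(_rec(np.arange(100.0), x, -x))
        zx = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(ns.values, 2 * zx, atol=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        s, i = rng.normal(size=10), rng.normal(size=10)
        ns = ofp.compute_zdiff(_rec(np.arange(10.0), s, i))
        want = (s - s.mean()) / s.std(ddof=1) - (i - i.mean()) / i.std(ddof=1)
        assert np.allclose(ns.values, want, atol=1e-12)

    def test_zero_sd_fatal(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            ofp.compute_zdiff(_rec(np.arange(4.0), np.ones(4), [1, 2, 3, 4]))

    @given(st.integers(0, 2**31 - 1))
    def test_mean_is_zero(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(1.0, 0.3, 64)
        i = rng.normal(0.8, 0.2, 64)
        ns = ofp.compute_zdiff(_rec(np.arange(64.0), s, i))
        assert abs(ns.values.mean()) < 1e-10
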