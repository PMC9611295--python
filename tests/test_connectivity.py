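import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp

from plinet.connectivity import (
    ConnectivityTensor,
    WindowSpec,
    _pli_matrix_kernel,
    _pli_matrix_numpy,
    connectivity_tensor,
    count_windows,
    instantaneous_phase,
    mean_connectivity,
    pli,
    window_pli_matrices,
)
from plinet.preprocess import Recording

FS = 200.0


def rec_from(data, fs=FS):
    data = np.asarray(data, dtype=float)
    return Recording(data=data, fs=fs, labels=tuple(f"ch{i}" for i in range(len(data))))


class TestCountWindows:
    @pytest.mark.parametrize(
        "n_samples,length_s,step_s,expected",
        [
            (80_000, 4.0, 2.0, 199),  # the 400-s recording scheme
            (800, 4.0, 4.0, 1),
            (2_000, 4.0, 2.0, 4),  # starts at 0, 2, 4, 6 s
        ],
    )
    def test_counts(self, n_samples, length_s, step_s, expected):
        assert count_windows(n_samples, FS, WindowSpec(length_s, step_s)) == expected

    def test_too_short_recording(self):
        with pytest.raises(ValueError):
            count_windows(700, FS, WindowSpec(4.0, 2.0))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(2.0, 4.0)


class TestInstantaneousPhase:
    def test_cosine_phase_velocity(self):
        t = np.arange(0, 4.0, 1 / FS)
        phase = np.unwrap(instantaneous_phase(np.cos(2 * np.pi * 5.0 * t)))
        slope = np.polyfit(t[100:-100], phase[100:-100], 1)[0]
        assert abs(slope - 2 * np.pi * 5.0) / (2 * np.pi * 5.0) < 0.01

    def test_quadrature_pair_offset(self):
        t = np.arange(0, 4.0, 1 / FS)
        ps = instantaneous_phase(np.sin(2 * np.pi * 5.0 * t))
        pc = instantaneous_phase(np.cos(2 * np.pi * 5.0 * t))
        d = np.angle(np.exp(1j * (pc - ps)))[100:-100]
        assert np.all(np.abs(d - np.pi / 2) < 0.05)

    def test_all_zero_window_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))


class TestPli:
    t = np.arange(0, 4.0, 1 / FS)

    def test_identical_signals_give_zero(self):
        x = np.sin(2 * np.pi * 7.0 * self.t)
        assert pli(x, x) == 0.0

    def test_quarter_cycle_lag_gives_one(self):
        x = np.sin(2 * np.pi * 5.0 * self.t)
        y = np.sin(2 * np.pi * 5.0 * self.t - np.pi / 2)
        assert pli(x, y) == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("frac", [1 / 8, 1 / 4, 3 / 8])
    def test_consistent_sub_antiphase_lag_gives_one(self, frac):
        # a period-fraction shift of a pure sinusoid has constant Δφ sign
        # (exact antiphase sits on the ±π branch cut and is excluded)
        shift = int(round(frac * FS / 5.0))
        x = np.sin(2 * np.pi * 5.0 * self.t)
        y = np.roll(x, shift)
        assert pli(x[shift:-shift], y[shift:-shift]) == pytest.approx(1.0, abs=0.02)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 600))
        assert pli(x, y) == pytest.approx(pli(y, x), abs=1e-12)
        assert pli(3.7 * x, y) == pytest.approx(pli(x, y), abs=1e-12)
        assert pli(x, 0.01 * y) == pytest.approx(pli(x, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pli(np.ones(10), np.ones(11))

    def test_independent_noise_null_level(self):
        rng = np.random.default_rng(6)
        vals = [pli(*rng.normal(size=(2, 800))) for _ in range(200)]
        assert np.mean(np.asarray(vals) < 0.12) >= 0.95


def test_kernel_matches_numpy_reference():
    rng = np.random.default_rng(7)
    phases = rng.uniform(-np.pi, np.pi, size=(12, 500))
    assert np.array_equal(_pli_matrix_kernel(np.ascontiguousarray(phases)),
                          _pli_matrix_numpy(phases))


class TestWindowMatrices:
    def test_symmetric_zero_diagonal_unit_range(self):
        rng = np.random.default_rng(8)
        rec = rec_from(rng.normal(size=(6, 2000)))
        mats = window_pli_matrices(rec, WindowSpec(4.0, 2.0))
        assert mats.shape == (4, 6, 6)
        for m in mats:
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0.0)
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_identical_channels_give_zero_matrix(self):
        x = np.random.default_rng(9).normal(size=2000)
        rec = rec_from(np.tile(x, (4, 1)))
        mats = window_pli_matrices(rec, WindowSpec(4.0, 2.0))
        assert np.allclose(mats, 0.0)


class TestMeanConnectivity:
    def make_tensor(self, values):
        return ConnectivityTensor(bands=("beta",), values=np.asarray(values)[None])

    def test_identical_windows_reproduce_matrix(self):
        m = np.array([[0.0, 0.4], [0.4, 0.0]])
        tensor = self.make_tensor([m, m, m])
        assert np.allclose(mean_connectivity(tensor)["beta"], m)

    def test_two_window_average(self):
        zeros = np.zeros((2, 2))
        ones = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = mean_connectivity(self.make_tensor([zeros, ones]))["beta"]
        assert out[0, 1] == pytest.approx(0.5)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(size=(5, 4, 4))
        out = mean_connectivity(self.make_tensor(vals))["beta"]
        naive = sum(vals[w] for w in range(5)) / 5
        assert np.allclose(out, naive)

    def test_zero_windows_rejected(self):
        tensor = ConnectivityTensor(bands=("b",), values=np.empty((1, 0, 3, 3)))
        with pytest.raises(ValueError):
            mean_connectivity(tensor)


def test_connectivity_tensor_stacks_bands():
    rng = np.random.default_rng(11)
    recs = {
        "alpha": rec_from(rng.normal(size=(3, 1600))),
        "beta": rec_from(rng.normal(size=(3, 1600))),
    }
    tensor = connectivity_tensor(recs, WindowSpec(4.0, 2.0))
    assert tensor.bands == ("alpha", "beta")
    assert tensor.values.shape == (2, 3, 3, 3)
    assert np.array_equal(tensor.band("beta"), tensor.values[1])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st_hyp.integers(min_value=0, max_value=2**31 - 1))
def test_pli_bounds_property(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(2, 256))
    v = pli(x, y)
    assert 0.0 <= v <= 1.0
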