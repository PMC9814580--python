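"""Finite-field polarizabilities, ACF spectra, CUBE densities, Voronoi dipoles."""

import numpy as np
import pytest

from ramanmix import (
    DipoleTrace,
    PolarizabilityTrace,
    SpectrumEstimatorConfig,
    autocorrelation,
    finite_field_polarizability,
    power_spectrum,
    raman_from_polarizability,
    read_cube,
    tensor_invariant_series,
    voronoi_dipole,
)
from ramanmix.aimd_raman import (
    C_CM_S,
    write_cube,
    read_polarizability_csv,
    write_polarizability_csv,
)
from ramanmix.errors import (
    CubeParseError,
    DegenerateSpectrumError,
    InsufficientDataError,
    InvalidParameterError,
    TraceMismatchError,
)
from ramanmix.synthetic_data import SimConfig, gen_density_cube, gen_polarizability_trace


def _dipole_set(A, mu0, dt=0.5, field=5e-4):
    """Dipole traces exactly linear in the field: mu^(Ej) = mu0 + A E_j."""
    ref = DipoleTrace(dt, mu0)
    fielded = tuple(
        DipoleTrace(dt, mu0 + field * A[:, j][None, :].repeat(mu0.shape[0], axis=0),
                    field=tuple(field * np.eye(3)[j]))
        for j in range(3)
    )
    return ref, fielded


class TestFiniteField:
    def test_recovers_constant_tensor_exactly(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        A = 0.5 * (A + A.T)
        mu0 = rng.normal(size=(100, 3))
        ref, fielded = _dipole_set(A, mu0)
        trace = finite_field_polarizability(ref, fielded, 5e-4)
        assert np.max(np.abs(trace.tensors - A)) < 1e-10

    def test_reference_equal_fielded_gives_zero(self):
        mu0 = np.random.default_rng(3).normal(size=(50, 3))
        ref = DipoleTrace(0.5, mu0)
        trace = finite_field_polarizability(ref, (ref, ref, ref), 5e-4)
        assert np.all(trace.tensors == 0.0)

    def test_asymmetry_reported_and_symmetrized(self):
        A = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        mu0 = np.zeros((10, 3))
        ref, fielded = _dipole_set(A, mu0)
        trace = finite_field_polarizability(ref, fielded, 5e-4)
        assert trace.max_asymmetry == pytest.approx(np.max(np.abs(A - A.T)) / 2.0, rel=1e-9)
        np.testing.assert_allclose(trace.tensors[0], 0.5 * (A + A.T), atol=1e-12)

    def test_central_difference(self):
        A = np.diag([2.0, 3.0, 4.0])
        mu0 = np.random.default_rng(4).normal(size=(20, 3))
        field = 5e-4
        plus = tuple(DipoleTrace(0.5, mu0 + field * A[:, j]) for j in range(3))
        minus = tuple(DipoleTrace(0.5, mu0 - field * A[:, j]) for j in range(3))
        trace = finite_field_polarizability(
            DipoleTrace(0.5, mu0), plus, field, minus_fielded=minus
        )
        assert np.max(np.abs(trace.tensors - A)) < 1e-10

    def test_length_mismatch(self):
        ref = DipoleTrace(0.5, np.zeros((10, 3)))
        bad = DipoleTrace(0.5, np.zeros((11, 3)))
        with pytest.raises(TraceMismatchError):
            finite_field_polarizability(ref, (bad, bad, bad), 5e-4)

    def test_zero_field(self):
        ref = DipoleTrace(0.5, np.zeros((10, 3)))
        with pytest.raises(InvalidParameterError):
            finite_field_polarizability(ref, (ref, ref, ref), 0.0)


class TestInvariants:
    def test_isotropic_tensor(self):
        trace = PolarizabilityTrace(0.5, 3.0 * np.eye(3)[None].repeat(5, axis=0))
        iso, beta = tensor_invariant_series(trace)
        np.testing.assert_allclose(iso, 3.0)
        np.testing.assert_allclose(beta, 0.0, atol=1e-15)

    def test_traceless_tensor(self):
        t = np.diag([1.0, -1.0, 0.0])[None].repeat(4, axis=0)
        iso, _ = tensor_invariant_series(PolarizabilityTrace(0.5, t))
        np.testing.assert_allclose(iso, 0.0, atol=1e-15)

    def test_recomposition_identity(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(50, 3, 3))
        t = 0.5 * (t + np.transpose(t, (0, 2, 1)))
        trace = PolarizabilityTrace(0.5, t)
        iso, beta = tensor_invariant_series(trace)
        recomposed = iso[:, None, None] * np.eye(3) + beta
        assert np.max(np.abs(recomposed - t)) < 1e-12
        assert np.max(np.abs(np.trace(beta, axis1=1, axis2=2))) < 1e-12


class TestAutocorrelation:
    def test_cosine_closed_form(self):
        n = 10_000
        f = 0.01  # cycles per sample
        x = np.cos(2 * np.pi * f * np.arange(n))
        acf = autocorrelation(x, 500)
        tau = np.arange(501)
        assert np.max(np.abs(acf - 0.5 * np.cos(2 * np.pi * f * tau))) < 0.01

    def test_zero_lag_is_variance(self):
        x = np.random.default_rng(8).normal(size=2048)
        acf = autocorrelation(x, 10)
        assert acf[0] == pytest.approx(np.var(x), rel=1e-12)

    def test_white_noise_decorrelates(self):
        n = 10_000
        x = np.random.default_rng(12).normal(size=n)
        acf = autocorrelation(x, 50)
        assert np.max(np.abs(acf[1:])) < 5.0 / np.sqrt(n)

    def test_constant_series_all_zero(self):
        acf = autocorrelation(np.full(100, 3.7), 10)
        np.testing.assert_allclose(acf, 0.0, atol=1e-12)


class TestPowerSpectrum:
    def test_parseval_unwindowed(self):
        x = np.random.default_rng(21).normal(size=4096)
        freq, spec = power_spectrum(x, 0.5, window="none", max_lag=0.5, zero_pad_factor=1)
        m = 2 * 2048
        total = spec[0] + spec[-1] + 2.0 * spec[1:-1].sum()
        assert total / m == pytest.approx(np.var(x), rel=1e-6)

    def test_offset_invariance(self):
        x = np.random.default_rng(22).normal(size=2048)
        _, a = power_spectrum(x, 0.5)
        _, b = power_spectrum(x + 100.0, 0.5)
        np.testing.assert_allclose(a, b, atol=1e-6 * np.max(np.abs(a)))

    def test_pure_cosine_peak_within_one_bin(self):
        dt, n = 0.5, 8192
        nu = 1200.0  # cm^-1
        t = np.arange(n) * dt * 1e-15
        x = np.cos(2 * np.pi * C_CM_S * nu * t)
        freq, spec = power_spectrum(x, dt, window="hann", zero_pad_factor=4)
        bin_width = freq[1] - freq[0]
        assert abs(freq[np.argmax(spec)] - nu) <= bin_width


class TestRamanFromPolarizability:
    def test_single_mode_peak_position(self):
        trace, _ = gen_polarizability_trace(
            [(1000.0, 1.0, np.inf)], dt_fs=0.5, n=35_000, sim=SimConfig(seed=1)
        )
        spec = raman_from_polarizability(trace)
        peak = spec.grid[np.argmax(spec.intensities)]
        assert abs(peak - 1000.0) < 2.0

    def test_damping_time_halved_doubles_linewidth(self):
        def fwhm_of(tau_fs):
            trace, _ = gen_polarizability_trace(
                [(1000.0, 1.0, tau_fs)], dt_fs=0.5, n=35_000, sim=SimConfig(seed=1)
            )
            spec = raman_from_polarizability(
                trace, SpectrumEstimatorConfig(window="none", max_lag=0.9)
            )
            y, x = spec.intensities, spec.grid
            half = 0.5 * y.max()
            above = np.where(y >= half)[0]
            return x[above[-1]] - x[above[0]]

        w1, w2 = fwhm_of(500.0), fwhm_of(250.0)
        # Lorentzian width 1/(pi tau c): 21.2 and 42.4 cm^-1
        assert w2 / w1 == pytest.approx(2.0, rel=0.10)

    def test_two_mode_power_ratio(self):
        # amplitude ratio 2:1 -> power (area) ratio 4:1
        trace, _ = gen_polarizability_trace(
            [(800.0, 2.0, np.inf), (1200.0, 1.0, np.inf)],
            dt_fs=0.5, n=35_000, sim=SimConfig(seed=1),
        )
        spec = raman_from_polarizability(
            trace, SpectrumEstimatorConfig(window="hann")
        )
        x, y = spec.grid, spec.intensities
        area1 = np.trapezoid(y[(x > 750) & (x < 850)], x[(x > 750) & (x < 850)])
        area2 = np.trapezoid(y[(x > 1150) & (x < 1250)], x[(x > 1150) & (x < 1250)])
        assert area1 / area2 == pytest.approx(4.0, rel=0.10)

    def test_isotropic_trace_needs_iso_weight(self):
        trace, _ = gen_polarizability_trace(
            [(1000.0, 1.0, np.inf)], dt_fs=0.5, n=2048, sim=SimConfig(seed=1)
        )
        with pytest.raises(DegenerateSpectrumError):
            raman_from_polarizability(
                trace, SpectrumEstimatorConfig(invariant_weights=(0.0, 7.0))
            )

    def test_too_short_trace(self):
        trace = PolarizabilityTrace(0.5, np.zeros((32, 3, 3)))
        with pytest.raises(InsufficientDataError):
            raman_from_polarizability(trace)


@pytest.fixture
def gaussian_cube(tmp_path):
    cube, truth = gen_density_cube(
        [(np.array([6.0, 6.0, 6.0]), 1.2, 1.0)],
        origin=np.zeros(3),
        step=0.4,
        counts=(31, 31, 31),
        atoms=[("6", 6.0, np.array([6.0, 6.0, 6.0]))],
    )
    return cube, truth, tmp_path


class TestCube:
    def test_normalized_blob_integrates_to_one(self, gaussian_cube):
        cube, truth, _ = gaussian_cube
        assert cube.total_density() == pytest.approx(truth["total_charge"], abs=1e-3)

    def test_write_read_roundtrip_bytes(self, gaussian_cube):
        cube, _, tmp = gaussian_cube
        p1, p2 = tmp / "a.cube", tmp / "b.cube"
        write_cube(cube, p1)
        back = read_cube(p1)
        write_cube(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back.counts == cube.counts

    def test_negative_voxel_count_rejected(self, tmp_path):
        path = tmp_path / "bad.cube"
        path.write_text("c\nc\n 1 0.0 0.0 0.0\n -5 0.1 0 0\n 5 0 0.1 0\n 5 0 0 0.1\n"
                        " 6 6.0 0 0 0\n0.0\n")
        with pytest.raises(CubeParseError):
            read_cube(path)

    def test_value_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "short.cube"
        path.write_text("c\nc\n 1 0.0 0.0 0.0\n 2 0.1 0 0\n 2 0 0.1 0\n 2 0 0 0.1\n"
                        " 6 6.0 0 0 0\n0.0 0.0 0.0\n")
        with pytest.raises(CubeParseError):
            read_cube(path)


class TestVoronoiDipole:
    def test_symmetric_blob_zero_dipole(self, gaussian_cube):
        cube, _, _ = gaussian_cube
        center = np.array([6.0, 6.0, 6.0])
        dip = voronoi_dipole(cube, [0], center)
        # nuclear term Z(r_a - ref) = 0; electronic moment vanishes by symmetry
        assert np.max(np.abs(dip - np.array([6.0 * 0, 0, 0]))) < 1e-2

    def test_offset_blob_first_moment(self):
        # unit charge centered 0.5 bohr along x from the reference
        cube, _ = gen_density_cube(
            [(np.array([6.5, 6.0, 6.0]), 1.0, 1.0)],
            origin=np.zeros(3), step=0.4, counts=(31, 31, 31),
            atoms=[("1", 0.0, np.array([6.0, 6.0, 6.0]))],
        )
        dip = voronoi_dipole(cube, [0], np.array([6.0, 6.0, 6.0]))
        np.testing.assert_allclose(dip, [-0.5, 0.0, 0.0], atol=1e-2)

    def test_voronoi_assignment_excludes_far_blob(self):
        cube, _ = gen_density_cube(
            [(np.array([2.0, 2.0, 2.0]), 0.6, 1.0)],
            origin=np.zeros(3), step=0.4, counts=(26, 26, 26),
            atoms=[("1", 0.0, np.array([2.0, 2.0, 2.0])),
                   ("1", 0.0, np.array([8.0, 8.0, 8.0]))],
        )
        dip = voronoi_dipole(cube, [1], np.array([2.0, 2.0, 2.0]))
        assert np.max(np.abs(dip)) < 1e-3

    def test_empty_subset(self, gaussian_cube):
        cube, _, _ = gaussian_cube
        with pytest.raises(InvalidParameterError):
            voronoi_dipole(cube, [], np.zeros(3))


def test_polarizability_csv_roundtrip(tmp_path):
    trace, _ = gen_polarizability_trace(
        [(900.0, 1.0, np.inf)], dt_fs=0.5, n=128, sim=SimConfig(seed=3, noise_sigma=0.01)
    )
    path = tmp_path / "alpha.csv"
    write_polarizability_csv(trace, path)
    back = read_polarizability_csv(path)
    assert back.dt_fs == pytest.approx(0.5)
    np.testing.assert_allclose(back.tensors, trace.tensors, atol=1e-12)
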