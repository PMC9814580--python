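"""Raman spectra from ab initio molecular dynamics polarizability time series.

Instead of computing polarizability derivatives mode by mode, the Raman
spectrum of a dynamical system can be estimated directly as the Fourier
transform of the autocorrelation function (ACF) of the molecular
polarizability along a trajectory. This module provides that estimator plus
the two upstream steps: assembling per-frame polarizability tensors from
finite-field dipole traces (alpha_ij = [mu_i(E_j) - mu_i(0)] / E), and
integrating gridded electron densities (Gaussian CUBE files) over Voronoi
cells to obtain per-molecule dipoles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.constants import c as _C_M_S

from .errors import (
    CubeParseError,
    InsufficientDataError,
    InvalidParameterError,
    TraceMismatchError,
)
from .spectral_core import Spectrum

#: Speed of light in cm/s, for converting 1/s frequencies to wavenumbers.
C_CM_S = _C_M_S * 100.0


@dataclass(frozen=True)
class PolarizabilityTrace:
    """Time series of 3x3 symmetric polarizability tensors (a.u.) at fixed dt.

    ``tensors`` has shape (n, 3, 3); each tensor must be symmetric within
    1e-8 a.u. ``max_asymmetry`` records the largest |alpha - alpha^T|/2 seen
    before symmetrization (0 for directly constructed traces).
    """

    dt_fs: float
    tensors: np.ndarray
    max_asymmetry: float = 0.0

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise InvalidParameterError("dt must be positive")
        t = np.asarray(self.tensors, dtype=float)
        if t.ndim != 3 or t.shape[1:] != (3, 3):
            raise InvalidParameterError(f"tensors must be (n, 3, 3), got {t.shape}")
        asym = np.max(np.abs(t - np.transpose(t, (0, 2, 1))))
        if asym > 1e-8:
            raise InvalidParameterError(
                f"tensors not symmetric (max asymmetry {asym:.2e} a.u.); "
                "symmetrize via finite_field_polarizability"
            )
        object.__setattr__(self, "tensors", t)

    def __len__(self) -> int:
        return self.tensors.shape[0]


@dataclass(frozen=True)
class DipoleTrace:
    """Time series of dipole 3-vectors (a.u.) under an applied static field."""

    dt_fs: float
    vectors: np.ndarray
    field: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise InvalidParameterError("dt must be positive")
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidParameterError(f"vectors must be (n, 3), got {v.shape}")
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class SpectrumEstimatorConfig:
    """Knobs of the ACF -> Fourier-transform spectral estimator.

    window
        Lag window applied to the truncated ACF; 'hann' (default) trades a
        little resolution for strongly suppressed spectral leakage, 'none'
        keeps the raw truncated ACF (used for Parseval checks).
    max_lag
        Fraction of the series length used as maximum ACF lag (default 0.5).
    zero_pad_factor
        Interpolates the frequency axis by zero padding (default 4).
    invariant_weights
        (a_iso, a_aniso) weights of the isotropic and anisotropic scattering
        invariants; (45, 7) is the standard unpolarized combination
        45 alpha'^2 + 7 gamma'^2.
    quantum_correction
        'none' (default) or 'harmonic', the standard-harmonic frequency
        prefactor beta h c nu / (1 - exp(-beta h c nu)) applied to the
        classical spectrum.
    """

    window: str = "hann"
    max_lag: float = 0.5
    zero_pad_factor: int = 4
    invariant_weights: tuple[float, float] = (45.0, 7.0)
    quantum_correction: str = "none"
    temperature_k: float = 300.0

    def __post_init__(self):
        if not 0 < self.max_lag <= 1:
            raise InvalidParameterError("max_lag must be in (0, 1]")
        if self.zero_pad_factor < 1:
            raise InvalidParameterError("zero_pad_factor must be >= 1")
        if self.window not in ("none", "hann"):
            raise InvalidParameterError("window must be 'none' or 'hann'")
        a, b = self.invariant_weights
        if a < 0 or b < 0 or (a == 0 and b == 0):
            raise InvalidParameterError("invariant weights must be >= 0, not both 0")
        if self.quantum_correction not in ("none", "harmonic"):
            raise InvalidParameterError("quantum_correction must be 'none' or 'harmonic'")


# ---------------------------------------------------------------------------
# finite-field assembly


def finite_field_polarizability(
    reference: DipoleTrace,
    fielded: tuple[DipoleTrace, DipoleTrace, DipoleTrace],
    field_strength: float = 5e-4,
    minus_fielded: tuple[DipoleTrace, DipoleTrace, DipoleTrace] | None = None,
) -> PolarizabilityTrace:
    """Per-frame polarizability from dipole responses to a static field.

    Forward difference by default, alpha_ij(t) = [mu_i^{E_j}(t) - mu_i^0(t)]/E,
    with the field applied along x, y, z in turn (a field of 5e-4 a.u. is weak
    enough for the linear regime). If ``minus_fielded`` traces are supplied a
    central difference is used instead. The raw tensor is symmetrized as
    (alpha + alpha^T)/2 and the maximum asymmetry reported.
    """
    if field_strength <= 0:
        raise InvalidParameterError("field strength must be positive")
    traces = [reference, *fielded] + (list(minus_fielded) if minus_fielded else [])
    n, dt = len(reference), reference.dt_fs
    for tr in traces:
        if len(tr) != n or tr.dt_fs != dt:
            raise TraceMismatchError("all dipole traces must share dt and length")

    alpha = np.empty((n, 3, 3))
    for j in range(3):
        if minus_fielded is None:
            alpha[:, :, j] = (fielded[j].vectors - reference.vectors) / field_strength
        else:
            alpha[:, :, j] = (fielded[j].vectors - minus_fielded[j].vectors) / (
                2.0 * field_strength
            )
    asym = float(np.max(np.abs(alpha - np.transpose(alpha, (0, 2, 1))))) / 2.0
    sym = 0.5 * (alpha + np.transpose(alpha, (0, 2, 1)))
    return PolarizabilityTrace(dt_fs=dt, tensors=sym, max_asymmetry=asym)


def tensor_invariant_series(trace: PolarizabilityTrace) -> tuple[np.ndarray, np.ndarray]:
    """Split each tensor into isotropic mean and traceless anisotropic part.

    Returns (iso, beta) with iso(t) = tr(alpha)/3 and beta(t) = alpha - iso*I;
    alpha = iso*I + beta holds exactly and tr(beta) = 0 within 1e-12.
    """
    iso = np.trace(trace.tensors, axis1=1, axis2=2) / 3.0
    beta = trace.tensors - iso[:, None, None] * np.eye(3)
    return iso, beta


# ---------------------------------------------------------------------------
# spectral estimation


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean-removed ACF, unbiased at each lag.

    C(tau) = mean over overlapping pairs of dx(t) dx(t+tau), so C(0) is
    exactly the series variance. Computed via FFT with per-lag overlap-count
    normalization.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag >= n:
        raise InvalidParameterError(f"max_lag {max_lag} must be < series length {n}")
    dx = x - x.mean()
    m = 1 << int(np.ceil(np.log2(2 * n)))  # pad to avoid circular wrap
    f = np.fft.rfft(dx, m)
    acov = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1]
    return acov / (n - np.arange(max_lag + 1))


def power_spectrum(
    x: np.ndarray,
    dt_fs: float,
    window: str = "hann",
    max_lag: float = 0.5,
    zero_pad_factor: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a scalar series via the ACF route.

    The truncated ACF is (optionally) tapered with the positive-lag half of a
    Hann window, reflected to even symmetry, zero padded, and Fourier
    transformed. Frequencies are returned in cm^-1. For window='none' and
    zero_pad_factor=1 the mean of the returned spectrum equals the series
    variance (discrete Parseval identity).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    lag = max(1, int(round(max_lag * n)))
    lag = min(lag, n - 1)
    acf = autocorrelation(x, lag)
    if window == "hann":
        taper = 0.5 * (1.0 + np.cos(np.pi * np.arange(lag + 1) / lag))
        acf = acf * taper
    elif window != "none":
        raise InvalidParameterError("window must be 'none' or 'hann'")
    # even extension: [C0 .. CL, zeros, CL .. C1]
    m = int(2 * lag * zero_pad_factor)
    buf = np.zeros(m)
    buf[: lag + 1] = acf
    buf[-lag:] = acf[1:][::-1]
    spec = np.fft.rfft(buf).real
    freq_cm1 = np.arange(spec.size) / (m * dt_fs * 1e-15 * C_CM_S)
    return freq_cm1, spec


def raman_from_polarizability(
    trace: PolarizabilityTrace, config: SpectrumEstimatorConfig | None = None
) -> Spectrum:
    """Raman spectrum as the Fourier transform of the polarizability ACF.

    The isotropic invariant iso(t) = tr(alpha)/3 and the anisotropic
    components beta_ij(t) are autocorrelated separately; the spectrum is

        I(nu) propto a_iso * F[C_iso](nu) + a_aniso * F[C_gamma](nu),

    with C_gamma(tau) = (3/2) sum_ij <d beta_ij(t) d beta_ij(t+tau)> and
    (a_iso, a_aniso) = (45, 7) by default. The output is restricted to
    0-4000 cm^-1 and max-normalized.
    """
    if config is None:
        config = SpectrumEstimatorConfig()
    if len(trace) < 64:
        raise InsufficientDataError(f"need >= 64 samples, got {len(trace)}")
    iso, beta = tensor_invariant_series(trace)
    a_iso, a_aniso = config.invariant_weights

    freq, s_iso = power_spectrum(
        iso, trace.dt_fs, config.window, config.max_lag, config.zero_pad_factor
    )
    total = a_iso * s_iso
    if a_aniso > 0:
        s_gamma = np.zeros_like(s_iso)
        for i in range(3):
            for j in range(3):
                _, s_ij = power_spectrum(
                    beta[:, i, j], trace.dt_fs, config.window,
                    config.max_lag, config.zero_pad_factor,
                )
                s_gamma += s_ij
        total = total + a_aniso * 1.5 * s_gamma

    if config.quantum_correction == "harmonic":
        from .spectral_core import C2_CM_K

        with np.errstate(divide="ignore", invalid="ignore"):
            u = C2_CM_K * freq / config.temperature_k
            corr = np.where(freq > 0, u / (1.0 - np.exp(-u)), 1.0)
        total = total * corr

    mask = freq <= 4000.0
    freq, total = freq[mask], total[mask]
    total = np.clip(total, 0.0, None)
    peak = total.max()
    # rounding dust in the invariant split can leave ~eps^2-level power; treat
    # anything below a relative floor as no signal
    floor = 1e-10 * float(np.max(np.abs(trace.tensors))) ** 2
    if peak <= floor:
        from .errors import DegenerateSpectrumError

        raise DegenerateSpectrumError(
            "estimated spectrum is identically zero (no fluctuating invariant)"
        )
    return Spectrum(freq, total / peak, label="aimd")


# ---------------------------------------------------------------------------
# CUBE densities and Voronoi dipoles


@dataclass(frozen=True)
class CubeGrid:
    """A volumetric scalar field in the Gaussian CUBE convention.

    origin and axes in bohr; values in e/bohr^3, stored with the last axis
    fastest (Fortran record order of the format).
    """

    origin: np.ndarray
    axes: np.ndarray  # (3, 3) voxel step vectors, rows
    counts: tuple[int, int, int]
    atoms: list[tuple[str, float, np.ndarray]]  # (element symbol or Z str, charge, xyz bohr)
    values: np.ndarray  # shape counts

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def total_density(self) -> float:
        return float(self.values.sum() * self.voxel_volume)

    def voxel_centers(self) -> np.ndarray:
        """Coordinates of every voxel, shape (nx*ny*nz, 3), C order."""
        nx, ny, nz = self.counts
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
        return self.origin + idx @ self.axes


def read_cube(path) -> CubeGrid:
    """Parse a Gaussian CUBE file (2 comment lines, natoms+origin, 3 axes,
    atom records, whitespace-separated values in Fortran record order)."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    if len(lines) < 6:
        raise CubeParseError(f"{path}: truncated header")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(v) for v in head[1:4]])
    except (IndexError, ValueError) as exc:
        raise CubeParseError(f"{path}: bad natoms/origin record: {lines[2]!r}") from exc
    counts = []
    axes = []
    for r in range(3):
        parts = lines[3 + r].split()
        try:
            n = int(parts[0])
            vec = [float(v) for v in parts[1:4]]
        except (IndexError, ValueError) as exc:
            raise CubeParseError(f"{path}: bad axis record {r + 1}: {lines[3 + r]!r}") from exc
        if n <= 0:
            raise CubeParseError(f"{path}: non-positive voxel count in axis record {r + 1}")
        counts.append(n)
        axes.append(vec)
    atoms = []
    for a in range(abs(natoms)):
        parts = lines[6 + a].split()
        try:
            z = int(parts[0])
            charge = float(parts[1])
            pos = np.array([float(v) for v in parts[2:5]])
        except (IndexError, ValueError) as exc:
            raise CubeParseError(f"{path}: bad atom record {a + 1}") from exc
        atoms.append((str(z), charge, pos))
    body = " ".join(lines[6 + abs(natoms):])
    try:
        values = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise CubeParseError(f"{path}: unreadable value block") from exc
    expected = counts[0] * counts[1] * counts[2]
    if values.size != expected:
        raise CubeParseError(
            f"{path}: value block has {values.size} entries, header promises {expected}"
        )
    if not np.all(np.isfinite(values)):
        raise CubeParseError(f"{path}: non-finite density values")
    return CubeGrid(
        origin=origin,
        axes=np.array(axes),
        counts=tuple(counts),
        atoms=atoms,
        values=values.reshape(counts),
    )


def write_cube(cube: CubeGrid, path, comment: str = "ramanmix density") -> None:
    """Write a CubeGrid in the standard Gaussian CUBE layout."""
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("OUTER LOOP: X, MIDDLE: Y, INNER: Z\n")
        fh.write(
            f"{len(cube.atoms):5d} {cube.origin[0]:12.6f} {cube.origin[1]:12.6f} "
            f"{cube.origin[2]:12.6f}\n"
        )
        for n, ax in zip(cube.counts, cube.axes):
            fh.write(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
        for sym, charge, pos in cube.atoms:
            fh.write(
                f"{int(sym):5d} {charge:12.6f} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n"
            )
        flat = cube.values.ravel()
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v: .5E}" for v in flat[start:start + 6]) + "\n")


def voronoi_dipole(
    cube: CubeGrid, atom_subset: list[int], reference: np.ndarray
) -> np.ndarray:
    """Dipole (a.u.) of the molecule owning ``atom_subset``, by Voronoi cells.

    Each voxel is assigned to its nearest atom (plain Euclidean distance in
    the non-periodic box; ties go to the lowest atom index). The electronic
    term is -sum rho (r - reference) dV over voxels in the subset's cells;
    the nuclear term is +sum Z_a (r_a - reference) over the subset atoms.
    """
    if not atom_subset:
        raise InvalidParameterError("atom subset must be non-empty")
    reference = np.asarray(reference, dtype=float)
    atom_pos = np.array([pos for _, _, pos in cube.atoms])
    centers = cube.voxel_centers()
    # nearest atom per voxel; chunked to bound memory on large grids
    owner = np.empty(centers.shape[0], dtype=np.intp)
    chunk = 200_000
    for start in range(0, centers.shape[0], chunk):
        d2 = np.sum(
            (centers[start:start + chunk, None, :] - atom_pos[None, :, :]) ** 2, axis=2
        )
        owner[start:start + chunk] = np.argmin(d2, axis=1)  # argmin ties -> lowest index
    in_subset = np.isin(owner, np.asarray(atom_subset, dtype=np.intp))
    rho = cube.values.ravel()[in_subset]
    rvec = centers[in_subset] - reference
    electronic = -np.sum(rho[:, None] * rvec, axis=0) * cube.voxel_volume
    nuclear = np.zeros(3)
    for a in atom_subset:
        sym, charge, pos = cube.atoms[a]
        nuclear += charge * (pos - reference)
    return electronic + nuclear


# ---------------------------------------------------------------------------
# trace CSV I/O


def read_polarizability_csv(path, dt_fs: float | None = None) -> PolarizabilityTrace:
    """CSV with header t_fs,xx,xy,xz,yy,yz,zz (upper triangle, a.u.)."""
    df = pd.read_csv(path)
    need = ["t_fs", "xx", "xy", "xz", "yy", "yz", "zz"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    if dt_fs is None:
        t = df["t_fs"].to_numpy(float)
        if t.size < 2:
            raise InsufficientDataError(f"{path}: need >= 2 rows to infer dt")
        dt_fs = float(t[1] - t[0])
    n = len(df)
    tens = np.empty((n, 3, 3))
    tens[:, 0, 0] = df["xx"]
    tens[:, 0, 1] = tens[:, 1, 0] = df["xy"]
    tens[:, 0, 2] = tens[:, 2, 0] = df["xz"]
    tens[:, 1, 1] = df["yy"]
    tens[:, 1, 2] = tens[:, 2, 1] = df["yz"]
    tens[:, 2, 2] = df["zz"]
    return PolarizabilityTrace(dt_fs=dt_fs, tensors=tens)


def write_polarizability_csv(trace: PolarizabilityTrace, path) -> None:
    t = np.arange(len(trace)) * trace.dt_fs
    a = trace.tensors
    pd.DataFrame(
        {
            "t_fs": t,
            "xx": a[:, 0, 0], "xy": a[:, 0, 1], "xz": a[:, 0, 2],
            "yy": a[:, 1, 1], "yz": a[:, 1, 2], "zz": a[:, 2, 2],
        }
    ).to_csv(path, index=False)


def read_dipole_csv(path, dt_fs: float | None = None) -> DipoleTrace:
    """CSV with header t_fs,x,y,z (a.u.)."""
    df = pd.read_csv(path)
    need = ["t_fs", "x", "y", "z"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    if dt_fs is None:
        t = df["t_fs"].to_numpy(float)
        if t.size < 2:
            raise InsufficientDataError(f"{path}: need >= 2 rows to infer dt")
        dt_fs = float(t[1] - t[0])
    return DipoleTrace(dt_fs=dt_fs, vectors=df[["x", "y", "z"]].to_numpy(float))


def write_dipole_csv(trace: DipoleTrace, path) -> None:
    t = np.arange(len(trace)) * trace.dt_fs
    v = trace.vectors
    pd.DataFrame({"t_fs": t, "x": v[:, 0], "y": v[:, 1], "z": v[:, 2]}).to_csv(
        path, index=False
    )
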