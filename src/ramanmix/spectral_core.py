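"""Spectrum container and synthesis of broadened Raman spectra from harmonic modes.

A :class:`Spectrum` is the currency of every stage of the pipeline: a strictly
increasing wavenumber grid (cm^-1) with intensities in arbitrary Raman units.
Harmonic-mode tables (frequency, Raman activity) from quantum-chemical
calculations are turned into continuous spectra by scaling the frequencies,
converting activities to intensities for a given excitation wavelength and
temperature, and broadening each line with an area-normalized Lorentzian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.constants import physical_constants
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateSpectrumError,
    EmptyInputError,
    GridMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    UnsupportedModeError,
)

#: Second radiation constant h*c/k_B in cm*K (CODATA).
C2_CM_K = physical_constants["second radiation constant"][0] * 100.0


@dataclass(frozen=True)
class Spectrum:
    """An intensity curve sampled on a strictly increasing wavenumber grid.

    Parameters
    ----------
    grid : ndarray
        Wavenumbers in cm^-1, strictly increasing, length >= 2.
    intensities : ndarray
        Raman intensities (arbitrary units), same length as ``grid``.
    label : str
        Free-text label, e.g. a conformer region name such as ``"syn/south"``.
    """

    grid: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if grid.ndim != 1 or inten.ndim != 1 or grid.size != inten.size:
            raise InvalidParameterError(
                f"grid and intensities must be 1-D of equal length, "
                f"got {grid.shape} and {inten.shape}"
            )
        if grid.size < 2:
            raise InvalidParameterError("a spectrum needs at least 2 points")
        if not np.all(np.diff(grid) > 0):
            raise InvalidParameterError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.grid.size

    def with_intensities(self, intensities: np.ndarray, label: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, intensities, self.label if label is None else label)


@dataclass(frozen=True)
class HarmonicModeSet:
    """Discrete vibrational modes with Raman activities and optional intensities.

    Parameters
    ----------
    frequencies : ndarray
        Harmonic frequencies in cm^-1, all positive and finite.
    activities : ndarray
        Raman activities in A^4 amu^-1, non-negative.
    intensities : ndarray or None
        Raman intensities (arbitrary units); populated by
        :func:`activity_to_intensity`.
    scale_factor : float
        The frequency scaling factor already applied (1.0 = unscaled).
    """

    frequencies: np.ndarray
    activities: np.ndarray
    intensities: np.ndarray | None = None
    scale_factor: float = 1.0

    def __post_init__(self):
        freq = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        act = np.atleast_1d(np.asarray(self.activities, dtype=float))
        if freq.size != act.size:
            raise InvalidParameterError("frequencies and activities must align")
        if freq.size and (not np.all(np.isfinite(freq)) or np.any(freq <= 0)):
            raise InvalidParameterError("all frequencies must be positive and finite")
        if np.any(act < 0):
            raise InvalidParameterError("activities must be non-negative")
        inten = self.intensities
        if inten is not None:
            inten = np.atleast_1d(np.asarray(inten, dtype=float))
            if inten.size != freq.size:
                raise InvalidParameterError("intensities must align with frequencies")
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "activities", act)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class ConversionParams:
    """Excitation and thermal parameters for the activity -> intensity conversion.

    ``nu0`` is the excitation wavenumber 1e7 / lambda(nm) in cm^-1; 532 nm gives
    18796.99 cm^-1, well above any fundamental in the fingerprint region.
    """

    laser_wavelength_nm: float = 532.0
    temperature_k: float = 293.0

    def __post_init__(self):
        if self.laser_wavelength_nm <= 0:
            raise InvalidParameterError("laser wavelength must be positive")
        if self.temperature_k <= 0:
            raise InvalidParameterError("temperature must be positive")

    @property
    def nu0(self) -> float:
        """Excitation wavenumber in cm^-1."""
        return 1.0e7 / self.laser_wavelength_nm


@dataclass(frozen=True)
class GridSpec:
    """A regular wavenumber grid lo..hi (inclusive) with the given step, cm^-1."""

    lo: float = 600.0
    hi: float = 1600.0
    step: float = 0.5

    def __post_init__(self):
        if not (self.step > 0 and self.hi > self.lo):
            raise InvalidParameterError("need hi > lo and step > 0")

    def build(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        return self.lo + self.step * np.arange(n + 1)


@dataclass(frozen=True)
class BroadeningParams:
    """Lorentzian broadening width and target grid.

    ``fwhm`` is the full width at half maximum in cm^-1 (default 5, the
    intrinsic-lifetime width used for nucleoside spectra). The grid step must
    be at most fwhm/2 so the line shape is resolved.
    """

    fwhm: float = 5.0
    grid_spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        if self.fwhm <= 0:
            raise InvalidParameterError("fwhm must be positive")
        if self.grid_spec.step > self.fwhm / 2:
            raise InvalidParameterError(
                f"grid step {self.grid_spec.step} too coarse for fwhm {self.fwhm}; "
                "need step <= fwhm/2"
            )


# ---------------------------------------------------------------------------
# operations


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Cubic-spline resample a spectrum onto a new wavenumber grid.

    Points outside the input's domain get intensity 0 rather than an
    extrapolated spline value: downstream mixture fitting shifts and rescales
    sub-spectra, probing beyond their measured range, and extrapolated cubics
    diverge. Values at input nodes present in ``grid`` are reproduced exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise InvalidParameterError("target grid must be strictly increasing")
    if len(spectrum) < 4:
        raise InsufficientDataError(
            f"cubic-spline resampling needs >= 4 points, got {len(spectrum)}"
        )
    spline = CubicSpline(spectrum.grid, spectrum.intensities, extrapolate=False)
    out = spline(grid)
    out = np.where(np.isnan(out), 0.0, out)
    return Spectrum(grid, out, spectrum.label)


def normalize_max(spectrum: Spectrum, window: tuple[float, float] | None = None) -> Spectrum:
    """Divide intensities by their maximum over ``window`` (default: whole grid).

    Idempotent; raises :class:`DegenerateSpectrumError` if the in-window
    maximum is not positive.
    """
    if window is None:
        mask = slice(None)
    else:
        lo, hi = window
        mask = (spectrum.grid >= lo) & (spectrum.grid <= hi)
        if not np.any(mask):
            raise DegenerateSpectrumError("normalization window contains no points")
    peak = float(np.max(spectrum.intensities[mask]))
    if peak <= 0:
        raise DegenerateSpectrumError("maximum intensity in window is not positive")
    return spectrum.with_intensities(spectrum.intensities / peak)


def scale_frequencies(modes: HarmonicModeSet, factor: float) -> HarmonicModeSet:
    """Multiply every mode frequency by a positive scaling factor.

    Harmonic DFT frequencies are systematically high; a scaling factor below 1
    (method/basis dependent, supplied by the user) corrects them. Activities
    and intensities are unchanged.
    """
    if not factor > 0:
        raise InvalidParameterError(f"scaling factor must be positive, got {factor}")
    return replace(
        modes,
        frequencies=modes.frequencies * factor,
        scale_factor=modes.scale_factor * factor,
    )


def activity_to_intensity(
    modes: HarmonicModeSet, params: ConversionParams | None = None
) -> HarmonicModeSet:
    """Convert Raman activities to intensities for a given laser and temperature.

    Uses the standard differential-cross-section form

        I_i  propto  (nu0 - nu_i)^4 * S_i / { nu_i * [1 - exp(-c2 nu_i / T)] }

    with nu0 the excitation wavenumber and c2 = h c / k_B the second radiation
    constant in cm K. The overall prefactor is irrelevant because spectra are
    max-normalized downstream.
    """
    if params is None:
        params = ConversionParams()
    nu = modes.frequencies
    if np.any(nu >= params.nu0):
        raise UnsupportedModeError(
            f"mode frequency >= excitation wavenumber {params.nu0:.1f} cm^-1"
        )
    boltzmann = 1.0 - np.exp(-C2_CM_K * nu / params.temperature_k)
    inten = (params.nu0 - nu) ** 4 * modes.activities / (nu * boltzmann)
    return replace(modes, intensities=inten)


def lorentzian_broaden(modes: HarmonicModeSet, params: BroadeningParams | None = None) -> Spectrum:
    """Broaden discrete modes into a continuous spectrum with Lorentzian lines.

    Each line is area-normalized, (Gamma/2pi) / [(nu - nu_i)^2 + (Gamma/2)^2],
    then scaled by the mode intensity, so the integrated area of the spectrum
    equals the summed intensities. For a uniform Gamma this differs from
    height scaling only by a global constant that max-normalization removes.
    """
    if params is None:
        params = BroadeningParams()
    if len(modes) == 0:
        raise EmptyInputError("cannot broaden an empty mode set")
    if modes.intensities is None:
        raise InvalidParameterError(
            "mode intensities not populated; call activity_to_intensity first"
        )
    grid = params.grid_spec.build()
    half = params.fwhm / 2.0
    delta = grid[:, None] - modes.frequencies[None, :]
    lines = (params.fwhm / (2.0 * np.pi)) / (delta**2 + half**2)
    return Spectrum(grid, lines @ modes.intensities)


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing one grid.

    This is the ensemble average over per-conformer spectra (e.g. 1000
    conformations sampled from a simulated Boltzmann distribution). Spectra on
    different grids must be resampled first.
    """
    if not spectra:
        raise EmptyInputError("no spectra to average")
    ref = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.size != ref.size or not np.array_equal(s.grid, ref):
            raise GridMismatchError("all spectra must share one wavenumber grid")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return Spectrum(ref, mean, spectra[0].label)


# ---------------------------------------------------------------------------
# I/O


def read_spectrum(path, label: str = "") -> Spectrum:
    """Read a two-column (wavenumber, intensity) text spectrum.

    Whitespace- or comma-delimited; lines starting with ``#`` are comments.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise InvalidParameterError(f"bad spectrum line in {path}: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 data rows")
    arr = np.asarray(rows)
    order = np.argsort(arr[:, 0])
    return Spectrum(arr[order, 0], arr[order, 1], label or str(path))


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text with 6 significant digits."""
    with open(path, "w") as fh:
        if spectrum.label:
            fh.write(f"# {spectrum.label}\n")
        fh.write("# wavenumber_cm1 intensity\n")
        for x, y in zip(spectrum.grid, spectrum.intensities):
            fh.write(f"{x:.6g} {y:.6g}\n")


def read_mode_table(path) -> HarmonicModeSet:
    """Read a CSV mode table with header ``frequency_cm1,activity`` (or ``intensity``)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "frequency_cm1" not in cols:
        raise InvalidParameterError(f"{path}: missing 'frequency_cm1' column")
    freq = df[cols["frequency_cm1"]].to_numpy(float)
    act = df[cols["activity"]].to_numpy(float) if "activity" in cols else np.zeros_like(freq)
    inten = df[cols["intensity"]].to_numpy(float) if "intensity" in cols else None
    return HarmonicModeSet(freq, act, inten)


def write_mode_table(modes: HarmonicModeSet, path) -> None:
    data = {"frequency_cm1": modes.frequencies, "activity": modes.activities}
    if modes.intensities is not None:
        data["intensity"] = modes.intensities
    pd.DataFrame(data).to_csv(path, index=False)
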