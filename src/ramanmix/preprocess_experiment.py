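"""Preprocessing of measured Raman spectra.

Raw solution spectra carry a solvent contribution and a slowly varying
baseline (fluorescence, quartz, detector drift). The pipeline is: subtract an
identically acquired water background, remove the remaining baseline by
asymmetric least squares (AsLS), and truncate to the analysis window
(600-1600 cm^-1 by default; above 1600 cm^-1 the water background makes
baseline correction unreliable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import GridMismatchError, InvalidParameterError, WindowError
from .spectral_core import Spectrum


@dataclass(frozen=True)
class BaselineConfig:
    """AsLS baseline parameters.

    p
        Asymmetry: weight of points above the running baseline (peaks);
        points below get weight 1 - p. Small p (default 0.01) makes the
        baseline hug the troughs under the peaks.
    lam
        Smoothness of the Whittaker smoother's second-difference penalty
        (default 1e5); larger values give stiffer baselines.
    iterations
        Number of reweighting passes (default 10).
    polynomial_degree
        Degree for the polynomial-basis variant (default 3).
    mode
        'whittaker' (default) or 'polynomial'. The Whittaker smoother is the
        method the AsLS literature describes; the polynomial variant fits a
        low-order polynomial under the same asymmetric reweighting.
    """

    p: float = 0.01
    lam: float = 1.0e5
    iterations: int = 10
    polynomial_degree: int = 3
    mode: str = "whittaker"

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise InvalidParameterError("asymmetry p must be in (0, 1)")
        if self.lam <= 0:
            raise InvalidParameterError("smoothness lambda must be positive")
        if self.iterations < 1:
            raise InvalidParameterError("need at least one iteration")
        if self.mode not in ("whittaker", "polynomial"):
            raise InvalidParameterError("mode must be 'whittaker' or 'polynomial'")


def subtract_background(
    sample: Spectrum, background: Spectrum, scale: float = 1.0
) -> Spectrum:
    """Subtract ``scale`` times a background spectrum measured on the same grid.

    With ``scale=None`` the least-squares-optimal scale
    <sample, background> / <background, background> is used instead of 1.
    """
    if sample.grid.size != background.grid.size or not np.allclose(
        sample.grid, background.grid
    ):
        raise GridMismatchError(
            "background must be resampled onto the sample grid before subtraction"
        )
    if scale is None:
        denom = float(np.dot(background.intensities, background.intensities))
        if denom == 0:
            raise InvalidParameterError("cannot auto-scale an all-zero background")
        scale = float(np.dot(sample.intensities, background.intensities)) / denom
    return sample.with_intensities(sample.intensities - scale * background.intensities)


def asls_baseline(
    spectrum: Spectrum, config: BaselineConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Asymmetric-least-squares baseline; returns (baseline, corrected).

    Iteratively reweighted penalized least squares: at each pass the baseline
    z minimizes sum_i v_i (y_i - z_i)^2 + lam * sum (second differences)^2
    with v_i = p where y_i > z_i and 1 - p otherwise, so peaks barely pull the
    baseline up while troughs anchor it. The polynomial mode replaces the
    Whittaker smoother with a degree-``polynomial_degree`` fit under the same
    reweighting.
    """
    if config is None:
        config = BaselineConfig()
    y = spectrum.intensities
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError("spectrum intensities must be finite")
    if len(spectrum) < 10:
        raise InvalidParameterError("baseline estimation needs >= 10 points")

    n = y.size
    w = np.ones(n)
    if config.mode == "whittaker":
        d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
        penalty = config.lam * (d.T @ d)
        for _ in range(config.iterations):
            wmat = sparse.diags(w, 0, format="csc")
            z = spsolve(wmat + penalty, w * y)
            w = np.where(y > z, config.p, 1.0 - config.p)
    else:
        x = spectrum.grid
        span = float(np.ptp(x))
        xc = (x - x.mean()) / (span if span > 0 else 1.0)
        for _ in range(config.iterations):
            coeffs = np.polynomial.polynomial.polyfit(
                xc, y, config.polynomial_degree, w=np.sqrt(w)
            )
            z = np.polynomial.polynomial.polyval(xc, coeffs)
            w = np.where(y > z, config.p, 1.0 - config.p)

    baseline = spectrum.with_intensities(np.asarray(z), label="baseline")
    corrected = spectrum.with_intensities(y - np.asarray(z))
    return baseline, corrected


def truncate_window(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep points with lo <= wavenumber <= hi."""
    if lo >= hi:
        raise InvalidParameterError("need lo < hi")
    mask = (spectrum.grid >= lo) & (spectrum.grid <= hi)
    if np.count_nonzero(mask) < 2:
        raise WindowError(f"window [{lo}, {hi}] retains fewer than 2 points")
    return Spectrum(spectrum.grid[mask], spectrum.intensities[mask], spectrum.label)
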