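"""Seeded generators for every input the pipeline consumes, with ground truth.

The simulated trajectories, polarizability time series and laboratory spectra
behind a real nucleoside study are too expensive to regenerate, so the test
and validation surface of this package is built on synthetic stand-ins with
known generating truth: analytic peak sets for sub-spectra, the forward
mixture model for observations, a discrete-time two-or-more-state Markov
chain (with optional continuous torsion series) for conformer exchange,
damped-cosine tensor traces for polarizabilities, and Gaussian blobs for
electron densities. Every generator is a pure function of its parameters and
seed, and can emit a JSON truth sidecar for downstream recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .aimd_raman import CubeGrid, PolarizabilityTrace
from .conformer_analysis import ConformerLabelSeries, ring_torsions_from_pucker
from .errors import InvalidParameterError, TimestepError
from .mixture_fit import SubSpectrumSet, conformer_prediction
from .spectral_core import GridSpec, Spectrum, normalize_max


@dataclass(frozen=True)
class PeakSpec:
    """One analytic spectral line."""

    center: float
    height: float = 1.0
    fwhm: float = 10.0
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise InvalidParameterError("fwhm must be positive")
        if self.height < 0:
            raise InvalidParameterError("height must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise InvalidParameterError("shape must be 'lorentzian' or 'gaussian'")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        half = self.fwhm / 2.0
        if self.shape == "lorentzian":
            return self.height * half**2 / ((x - self.center) ** 2 + half**2)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.height * np.exp(-0.5 * ((x - self.center) / sigma) ** 2)


@dataclass(frozen=True)
class SimConfig:
    """Seed, noise level and grid shared by the generators."""

    seed: int = 0
    noise_sigma: float = 0.0
    grid_spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")


#: Three well-separated Lorentzian peaks per conformer; tolerances in weight
#: recovery are then attributable to the optimizer, not to identifiability.
SEPARATED_PRESET = (
    (PeakSpec(740, 1.0, 12), PeakSpec(1100, 0.6, 10), PeakSpec(1340, 0.9, 12)),
    (PeakSpec(820, 0.8, 12), PeakSpec(1000, 1.0, 10), PeakSpec(1480, 0.7, 12)),
    (PeakSpec(680, 0.7, 12), PeakSpec(1240, 1.0, 10), PeakSpec(1560, 0.5, 12)),
)

#: Heavily overlapping peaks; probes the hard identifiability regime.
OVERLAPPING_PRESET = (
    (PeakSpec(1000, 1.0, 30), PeakSpec(1050, 0.8, 30), PeakSpec(1300, 0.6, 25)),
    (PeakSpec(1010, 0.9, 30), PeakSpec(1060, 1.0, 30), PeakSpec(1310, 0.5, 25)),
    (PeakSpec(1020, 0.7, 30), PeakSpec(1070, 0.9, 30), PeakSpec(1290, 1.0, 25)),
)


def gen_subspectrum(peaks, sim: SimConfig, label: str = "synthetic") -> Spectrum:
    """Sum of analytic line shapes plus Gaussian noise, max-normalized."""
    if not peaks:
        raise InvalidParameterError("need at least one peak")
    rng = np.random.default_rng(sim.seed)
    grid = sim.grid_spec.build()
    y = np.zeros_like(grid)
    for p in peaks:
        y += p.evaluate(grid)
    if sim.noise_sigma > 0:
        y = y + rng.normal(0.0, sim.noise_sigma, grid.size)
    return normalize_max(Spectrum(grid, y, label=label))


def gen_mixture_observation(
    subs: list[Spectrum], w, r, s: float, sim: SimConfig
) -> tuple[Spectrum, dict]:
    """Forward mixture model: y_i = sum_j w_j f^j(r_j x_i + s) + noise.

    Returns the observation and a JSON-serializable truth record holding the
    generating (w, r, s) and noise level.
    """
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    if not (len(subs) == w.size == r.size):
        raise InvalidParameterError("subs, w and r must align")
    rng = np.random.default_rng(sim.seed)
    sset = SubSpectrumSet(tuple(subs))
    grid = sim.grid_spec.build()
    y = np.zeros_like(grid)
    for j in range(len(subs)):
        y += w[j] * conformer_prediction(sset.spline(j), float(r[j]), s, grid)
    if sim.noise_sigma > 0:
        y = y + rng.normal(0.0, sim.noise_sigma, grid.size)
    truth = {
        "w": w.tolist(),
        "r": r.tolist(),
        "s": float(s),
        "noise_sigma": sim.noise_sigma,
        "seed": sim.seed,
        "labels": [sp.label for sp in subs],
    }
    return Spectrum(grid, y, label="observation"), truth


def gen_conformer_chain(
    rates_per_ns: dict[tuple[str, str], float],
    frame_interval_ps: float,
    n_frames: int,
    sim: SimConfig,
    states: tuple[str, ...] | None = None,
    with_torsions: bool = False,
    angular_noise_deg: float = 8.0,
) -> tuple[ConformerLabelSeries, dict]:
    """Discrete-time Markov chain over conformer labels.

    Per-frame transition probability for a -> b is 1 - exp(-k_ab * dt) (exact
    for a two-state exchange observed at interval dt when rates are per ns).
    With ``with_torsions`` the series also carries continuous chi and P drawn
    from wrapped Gaussians around label-dependent means (chi near 0 for syn,
    180 for anti; P near 162 for south, 18 for north — the c2'-endo and
    c3'-endo centers), enabling round trips through the classifier.
    """
    if n_frames < 2:
        raise InvalidParameterError("need at least 2 frames")
    if any(k < 0 for k in rates_per_ns.values()):
        raise InvalidParameterError("rates must be >= 0")
    if states is None:
        states = tuple(sorted({s for pair in rates_per_ns for s in pair}))
        if not states:
            raise InvalidParameterError("no states given")
    dt_ns = frame_interval_ps / 1000.0
    nstates = len(states)
    idx = {s: i for i, s in enumerate(states)}

    probs = np.zeros((nstates, nstates))
    for (a, b), k in rates_per_ns.items():
        probs[idx[a], idx[b]] = 1.0 - np.exp(-k * dt_ns)
    stay = 1.0 - probs.sum(axis=1)
    if np.any(stay < 0):
        raise TimestepError(
            "total per-frame exit probability exceeds 1; reduce frame interval"
        )
    probs[np.arange(nstates), np.arange(nstates)] = stay

    rng = np.random.default_rng(sim.seed)
    labels_idx = np.empty(n_frames, dtype=np.intp)
    labels_idx[0] = rng.integers(nstates)
    u = rng.random(n_frames - 1)
    cum = np.cumsum(probs, axis=1)
    for t in range(1, n_frames):
        labels_idx[t] = np.searchsorted(cum[labels_idx[t - 1]], u[t - 1])
    labels = tuple(states[i] for i in labels_idx)

    chi = P = None
    if with_torsions:
        chi_mean = {"syn": 0.0, "anti": 180.0}
        p_mean = {"south": 162.0, "north": 18.0}
        chi0 = np.array([chi_mean[lab.split("/")[0]] for lab in labels])
        p0 = np.array([p_mean[lab.split("/")[1]] for lab in labels])
        chi = chi0 + rng.normal(0.0, angular_noise_deg, n_frames)
        P = p0 + rng.normal(0.0, angular_noise_deg, n_frames)
        chi = (chi + 180.0) % 360.0 - 180.0
        P = P % 360.0

    truth = {
        "states": list(states),
        "rates_per_ns": {f"{a}->{b}": k for (a, b), k in rates_per_ns.items()},
        "frame_interval_ps": frame_interval_ps,
        "n_frames": n_frames,
        "seed": sim.seed,
    }
    return (
        ConformerLabelSeries(labels=labels, frame_interval_ps=frame_interval_ps,
                             chi=chi, P=P),
        truth,
    )


def torsions_for_labels(series: ConformerLabelSeries, tau_m: float = 40.0) -> np.ndarray:
    """Five ring torsions per frame from the series' continuous P values."""
    if series.P is None:
        raise InvalidParameterError("series carries no continuous P values")
    return np.stack([ring_torsions_from_pucker(p, tau_m) for p in series.P])


def gen_polarizability_trace(
    modes: list[tuple[float, float, float]],
    dt_fs: float,
    n: int,
    sim: SimConfig,
    tensors: list[np.ndarray] | None = None,
) -> tuple[PolarizabilityTrace, dict]:
    """Damped-cosine tensor trace emulating an AIMD polarizability output.

    ``modes`` is a list of (wavenumber cm^-1, amplitude, damping time fs; use
    inf for undamped). Each mode modulates a fixed symmetric unit tensor M_k
    (isotropic identity by default); Gaussian noise of sd ``noise_sigma`` is
    added independently to the six unique components.
    """
    if dt_fs <= 0:
        raise InvalidParameterError("dt must be positive")
    from .aimd_raman import C_CM_S

    rng = np.random.default_rng(sim.seed)
    t_s = np.arange(n) * dt_fs * 1e-15
    alpha = np.zeros((n, 3, 3))
    if tensors is None:
        tensors = [np.eye(3)] * len(modes)
    for (nu_cm1, amp, tau_fs), M in zip(modes, tensors):
        M = 0.5 * (np.asarray(M, float) + np.asarray(M, float).T)
        osc = amp * np.cos(2.0 * np.pi * C_CM_S * nu_cm1 * t_s)
        if np.isfinite(tau_fs):
            osc = osc * np.exp(-t_s / (tau_fs * 1e-15))
        alpha += osc[:, None, None] * M
    if sim.noise_sigma > 0:
        noise = rng.normal(0.0, sim.noise_sigma, (n, 3, 3))
        alpha += 0.5 * (noise + np.transpose(noise, (0, 2, 1)))
    truth = {
        "modes": [[m[0], m[1], m[2] if np.isfinite(m[2]) else None] for m in modes],
        "dt_fs": dt_fs,
        "n": n,
        "seed": sim.seed,
    }
    return PolarizabilityTrace(dt_fs=dt_fs, tensors=alpha), truth


def gen_density_cube(
    blobs: list[tuple[np.ndarray, float, float]],
    origin: np.ndarray,
    step: float,
    counts: tuple[int, int, int],
    atoms: list[tuple[str, float, np.ndarray]],
    sim: SimConfig | None = None,
) -> tuple[CubeGrid, dict]:
    """Sum of normalized Gaussian blobs sampled on a cubic voxel grid.

    ``blobs`` is a list of (center bohr, width sigma bohr, charge e). The
    analytic total charge and first moment are recorded as truth; a blob whose
    center lies further than 5 sigma outside the box is tolerated with a
    warning (its integrated charge will be truncated).
    """
    import warnings

    origin = np.asarray(origin, dtype=float)
    axes = np.eye(3) * step
    nx, ny, nz = counts
    xs = origin[0] + step * np.arange(nx)
    ys = origin[1] + step * np.arange(ny)
    zs = origin[2] + step * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    values = np.zeros(counts, dtype=float)
    hi = origin + step * (np.asarray(counts) - 1)
    for center, sigma, charge in blobs:
        center = np.asarray(center, dtype=float)
        if sigma <= 0:
            raise InvalidParameterError("blob width must be positive")
        if np.any(center < origin - 5 * sigma) or np.any(center > hi + 5 * sigma):
            warnings.warn("blob center > 5 sigma outside the box; charge truncated")
        norm = charge / (sigma**3 * (2.0 * np.pi) ** 1.5)
        values += norm * np.exp(
            -((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
            / (2.0 * sigma**2)
        )
    total = sum(b[2] for b in blobs)
    moment = (
        sum(b[2] * np.asarray(b[0], float) for b in blobs) / total
        if total != 0
        else np.zeros(3)
    )
    truth = {
        "total_charge": total,
        "charge_center": np.asarray(moment, float).tolist(),
        "blobs": [[list(np.asarray(c, float)), s, q] for c, s, q in blobs],
    }
    return (
        CubeGrid(origin=origin, axes=axes, counts=tuple(counts), atoms=list(atoms),
                 values=values),
        truth,
    )


def write_truth(truth: dict, path) -> None:
    """Write a ground-truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
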