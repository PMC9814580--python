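"""Conformer classification of nucleoside trajectories.

The conformational space of a ribonucleoside is reduced to two degrees of
freedom: the glycosidic torsion chi (base orientation, O4'-C1'-N9-C4 for
purines, O4'-C1'-N1-C2 for pyrimidines) and the ribose ring pucker, summarized
by the pseudorotation phase angle P computed from the five endocyclic torsions
by the Altona-Sundaralingam construction. Frames are labelled
{syn, anti} x {north, south}; label series yield populations and exchange
kinetics (transition rates in ns^-1, mean conformer lifetimes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .errors import (
    FlatRingError,
    InsufficientDataError,
    InvalidParameterError,
    MalformedTrajectoryError,
    UndefinedDihedralError,
)

SYN, ANTI = "syn", "anti"
NORTH, SOUTH = "north", "south"
#: The four conformer labels, chi-state x pucker-state.
LABELS = ("syn/south", "syn/north", "anti/south", "anti/north")

_SIN36_PLUS_SIN72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))


@dataclass(frozen=True)
class TorsionSpec:
    """Atom indices (0-based) defining chi and the five ring torsions.

    ``ring_atoms`` lists C4', O4', C1', C2', C3' in order; the endocyclic
    torsions nu0..nu4 are formed by sliding a 4-atom window cyclically:
    nu0 = C4'-O4'-C1'-C2', ..., nu2 = C1'-C2'-C3'-C4' (the reference torsion),
    nu4 = C3'-C4'-O4'-C1'. With this indexing P ~ 18 deg is c3'-endo (north)
    and P ~ 162 deg is c2'-endo (south).
    """

    chi_atoms: tuple[int, int, int, int]
    ring_atoms: tuple[int, int, int, int, int]
    base_class: str = "purine"

    def __post_init__(self):
        if len(self.chi_atoms) != 4 or len(self.ring_atoms) != 5:
            raise InvalidParameterError("need 4 chi atoms and 5 ring atoms")
        all_idx = tuple(self.chi_atoms) + tuple(self.ring_atoms)
        if any(i < 0 for i in all_idx):
            raise InvalidParameterError("atom indices must be non-negative")
        if len(set(self.chi_atoms)) != 4 or len(set(self.ring_atoms)) != 5:
            raise InvalidParameterError("atom indices within a torsion set must be distinct")
        if self.base_class not in ("purine", "pyrimidine"):
            raise InvalidParameterError("base_class must be 'purine' or 'pyrimidine'")

    @classmethod
    def from_json(cls, path) -> "TorsionSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            chi_atoms=tuple(d["chi_atoms"]),
            ring_atoms=tuple(d["ring_atoms"]),
            base_class=d.get("base_class", "purine"),
        )

    def nu_quads(self) -> list[tuple[int, int, int, int]]:
        """The five 4-atom index windows for nu0..nu4."""
        r = list(self.ring_atoms)
        return [tuple(r[(j + k) % 5] for k in range(4)) for j in range(5)]


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase P (deg, [0, 360)) and amplitude tau_m (deg, >= 0)."""

    P: float
    tau_m: float


@dataclass(frozen=True)
class ConformerLabelSeries:
    """Per-frame conformer labels at a fixed frame interval.

    ``chi`` and ``P`` optionally carry the underlying angle series (degrees)
    so that kinetics can re-classify with a hysteresis buffer.
    """

    labels: tuple[str, ...]
    frame_interval_ps: float
    chi: np.ndarray | None = None
    P: np.ndarray | None = None

    def __post_init__(self):
        if len(self.labels) == 0:
            raise InvalidParameterError("label series must be non-empty")
        if self.frame_interval_ps <= 0:
            raise InvalidParameterError("frame interval must be positive")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PopulationTable:
    """Conformer fractions summing to 1."""

    fractions: dict[str, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise InvalidParameterError(f"fractions sum to {total}, not 1")

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.fractions.items()}


@dataclass(frozen=True)
class RateTable:
    """First-order exchange rates k[a->b] (ns^-1) and mean lifetimes (ns)."""

    rates: dict[tuple[str, str], float]
    mean_lifetimes: dict[str, float]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees, in (-180, 180].

    IUPAC sign convention: positive when the far bond p3->p4 is rotated
    clockwise relative to the near bond p2->p1, viewed from p2 toward p3.
    Computed with the atan2 form, which is numerically stable near 0/180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)  # normal of the p1-p2-p3 plane
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedDihedralError("collinear or coincident atoms in dihedral")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def _dihedral_batch(coords: np.ndarray, quad: tuple[int, int, int, int]) -> np.ndarray:
    """Vectorized dihedral over frames; coords is (n_frames, n_atoms, 3)."""
    p1, p2, p3, p4 = (coords[:, i, :] for i in quad)
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.linalg.norm(b2, axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0 + 1e-12] = 180.0
    return ang


def pseudorotation(nu) -> PuckerState:
    """Pseudorotation phase and amplitude from the five ring torsions (Altona).

    Inverts the generating relation nu_j = tau_m * cos(P + 144 deg * (j - 2)):

        tan P = [(nu4 + nu1) - (nu3 + nu0)] / [2 nu2 (sin 36 + sin 72)]

    with the quadrant resolved by atan2 and tau_m recovered as the hypotenuse
    of (nu2, numerator / (2 (sin36 + sin72))), which is exact for any P
    including cos P = 0.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise InvalidParameterError("need exactly 5 torsions nu0..nu4")
    if np.all(np.abs(nu) < 1e-6):
        raise FlatRingError("all ring torsions vanish; pucker phase undefined")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    sin_term = num / (2.0 * _SIN36_PLUS_SIN72)  # = tau_m * sin(P)
    P = np.degrees(np.arctan2(sin_term, nu[2])) % 360.0
    tau_m = float(np.hypot(nu[2], sin_term))
    return PuckerState(P=float(P), tau_m=tau_m)


def ring_torsions_from_pucker(P: float, tau_m: float) -> np.ndarray:
    """Forward generating relation: nu_j = tau_m * cos(P + 144 deg * (j - 2))."""
    j = np.arange(5)
    return tau_m * np.cos(np.radians(P + 144.0 * (j - 2)))


def classify_conformer(chi: float, P: float, hysteresis: float = 0.0,
                       previous: str | None = None) -> str:
    """Assign a (chi, P) pair to one of the four conformer labels.

    syn iff chi in [-90, 90) after wrapping to (-180, 180]; south iff P in
    [90, 270) after wrapping to [0, 360). Boundaries are half-open so the
    classification is total and deterministic.

    With ``hysteresis`` > 0 and a ``previous`` label, the boundary is widened
    by that many degrees in favour of the previous state, suppressing
    rate inflation from rapid boundary recrossings.
    """
    if not (np.isfinite(chi) and np.isfinite(P)):
        raise InvalidParameterError("chi and P must be finite")
    chi = (chi + 180.0) % 360.0 - 180.0
    chi = 180.0 if chi == -180.0 else chi
    P = P % 360.0

    prev_chi = prev_puck = None
    if previous is not None and hysteresis > 0:
        prev_chi, prev_puck = previous.split("/")

    chi_state = SYN if -90.0 <= chi < 90.0 else ANTI
    if prev_chi is not None and chi_state != prev_chi:
        # distance past the nearest syn/anti boundary (at +-90 on the circle)
        excess = abs(abs(chi) - 90.0)
        if excess < hysteresis:
            chi_state = prev_chi

    puck_state = SOUTH if 90.0 <= P < 270.0 else NORTH
    if prev_puck is not None and puck_state != prev_puck:
        excess = min(abs(P - 90.0), abs(P - 270.0), abs(P - 450.0) % 360.0)
        if excess < hysteresis:
            puck_state = prev_puck

    return f"{chi_state}/{puck_state}"


def classify_series(chi: np.ndarray, P: np.ndarray, hysteresis: float = 0.0) -> list[str]:
    """Classify angle series frame-by-frame, threading the previous label."""
    labels: list[str] = []
    prev = None
    for c, p in zip(chi, P):
        prev = classify_conformer(float(c), float(p), hysteresis=hysteresis, previous=prev)
        labels.append(prev)
    return labels


# ---------------------------------------------------------------------------
# trajectories


def read_xyz_frames(path) -> np.ndarray:
    """Read a multi-frame XYZ file into an (n_frames, n_atoms, 3) array.

    Uses MDAnalysis, the field-standard trajectory reader; coordinates are
    returned in Angstrom as stored.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return frames


def torsion_series(frames: np.ndarray, spec: TorsionSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame chi, P, tau_m from a coordinate array (n_frames, n_atoms, 3)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise MalformedTrajectoryError(f"expected (n_frames, n_atoms, 3), got {frames.shape}")
    needed = max(max(spec.chi_atoms), max(spec.ring_atoms))
    if frames.shape[1] <= needed:
        raise MalformedTrajectoryError(
            f"trajectory has {frames.shape[1]} atoms but spec needs index {needed}"
        )
    chi = _dihedral_batch(frames, spec.chi_atoms)
    nus = np.stack([_dihedral_batch(frames, q) for q in spec.nu_quads()], axis=1)
    num = (nus[:, 4] + nus[:, 1]) - (nus[:, 3] + nus[:, 0])
    sin_term = num / (2.0 * _SIN36_PLUS_SIN72)
    P = np.degrees(np.arctan2(sin_term, nus[:, 2])) % 360.0
    tau_m = np.hypot(nus[:, 2], sin_term)
    return chi, P, tau_m


def label_trajectory(
    frames: np.ndarray,
    spec: TorsionSpec,
    stride: int = 1,
    frame_interval_ps: float = 10.0,
    hysteresis: float = 0.0,
) -> ConformerLabelSeries:
    """Label every ``stride``-th frame of a trajectory.

    The output frame interval is the input interval times the stride (e.g.
    10 ps frames at stride 50 give one label per 500 ps).
    """
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    chi, P, _ = torsion_series(np.asarray(frames, dtype=float)[::stride], spec)
    labels = classify_series(chi, P, hysteresis=hysteresis)
    return ConformerLabelSeries(
        labels=tuple(labels),
        frame_interval_ps=frame_interval_ps * stride,
        chi=chi,
        P=P,
    )


# ---------------------------------------------------------------------------
# populations & kinetics


def populations(series: ConformerLabelSeries) -> PopulationTable:
    """Label frequencies over the series; fractions sum to 1."""
    n = len(series)
    counts: dict[str, int] = {}
    for lab in series.labels:
        counts[lab] = counts.get(lab, 0) + 1
    return PopulationTable({k: v / n for k, v in counts.items()})


def transition_kinetics(
    series: ConformerLabelSeries, hysteresis: float | None = None
) -> RateTable:
    """Exchange rates and mean lifetimes from a label series.

    k[a->b] = (number of a->b label changes) / (total time spent in a, ns);
    mean_lifetime[a] = mean contiguous dwell time in a. If ``hysteresis`` is
    given and the series carries its chi/P angle series, frames are
    re-classified with that buffer before counting, which removes spurious
    boundary recrossings.
    """
    if len(series) < 2:
        raise InsufficientDataError("kinetics needs at least 2 frames")
    labels = list(series.labels)
    if hysteresis and series.chi is not None and series.P is not None:
        labels = classify_series(series.chi, series.P, hysteresis=hysteresis)

    dt_ns = series.frame_interval_ps / 1000.0
    time_in: dict[str, float] = {}
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(labels[:-1], labels[1:]):
        time_in[a] = time_in.get(a, 0.0) + dt_ns
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    # the final frame contributes residence but no transition opportunity
    time_in[labels[-1]] = time_in.get(labels[-1], 0.0)

    rates = {
        (a, b): counts.get((a, b), 0) / time_in[a]
        for a in time_in
        for b in set(labels)
        if a != b and time_in[a] > 0
    }

    lifetimes: dict[str, list[float]] = {}
    for lab, run in groupby(labels):
        lifetimes.setdefault(lab, []).append(sum(1 for _ in run) * dt_ns)
    mean_life = {k: float(np.mean(v)) for k, v in lifetimes.items()}
    return RateTable(rates=rates, mean_lifetimes=mean_life, counts=counts)
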