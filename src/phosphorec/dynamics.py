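"""Phosphate dihedral dynamics: circular distributions, rotamer states, kinetics.

The CB–OG–P–OT torsion tracks rotation of the phosphate group about the
ester bond.  In the unprotonated PO3^2- state the three terminal oxygens are
chemically equivalent, so the torsion hops between three rotamer wells 120°
apart; in PO3H- the oxygens are distinguishable and each well is chemically
distinct.  This module turns the per-frame torsion series into

* a normalised circular histogram over (-180, 180],
* a circularly-aware peak list (watershed basin masses),
* hard-core rotamer state assignments with an unassigned buffer zone, and
* hysteresis-filtered rotation-event counts and dwell-time statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import circular_difference, dihedral_array, wrap_angle
from .structure_io import ProtonationState, TrajectoryEnsemble

__all__ = [
    "DihedralSeries",
    "CircularHistogram",
    "Peak",
    "RotamerStateAssignment",
    "RotationKinetics",
    "UNASSIGNED",
    "dihedral_series",
    "circular_distribution",
    "detect_peaks",
    "assign_states",
    "rotation_events",
    "circular_mean",
]

#: Frame label for angles outside every rotamer core.
UNASSIGNED = -1


def circular_mean(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return wrap_angle(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))


@dataclass
class DihedralSeries:
    """Per-replicate torsion series (degrees in (-180, 180]) on retained frames."""

    replicates: list[np.ndarray] = field(default_factory=list)
    atom_quadruple: tuple[int, int, int, int] = (0, 1, 2, 3)
    protonation_state: ProtonationState = ProtonationState.PO3_2MINUS
    dt_ps: float = 100.0

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.replicates)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r, series in enumerate(self.replicates):
            for fi, v in enumerate(series):
                rows.append(
                    {"replicate": r, "time_ns": fi * self.dt_ps / 1000.0, "angle_deg": v}
                )
        return pd.DataFrame(rows)


def dihedral_series(
    ensemble: TrajectoryEnsemble,
    quad_indices: tuple[int, int, int, int],
) -> DihedralSeries:
    """Torsion angle of an atom quadruple (CB, OG, P, OT order) per retained frame."""
    if len(set(quad_indices)) != 4:
        raise ValueError(f"quadruple must be 4 distinct atom indices, got {quad_indices}")
    n = ensemble.topology.n_atoms
    for q in quad_indices:
        if not (0 <= q < n):
            raise ValueError(f"atom index {q} outside topology (n_atoms={n})")
    i, j, k, l = quad_indices
    out = DihedralSeries(
        replicates=[],
        atom_quadruple=tuple(quad_indices),
        protonation_state=ensemble.protonation_state,
        dt_ps=ensemble.dt_ps,
    )
    for r in range(ensemble.n_replicates):
        frames = ensemble.retained(r)
        out.replicates.append(
            np.asarray(dihedral_array(frames[:, i], frames[:, j], frames[:, k], frames[:, l]))
        )
    return out


@dataclass
class CircularHistogram:
    """Normalised circular density over (-180, 180]: sum(density)*bin_width = 1."""

    bin_centers: np.ndarray
    density: np.ndarray
    bin_width: float
    per_replicate: list[np.ndarray] = field(default_factory=list)
    n_samples: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center_deg": self.bin_centers, "density": self.density})


def circular_distribution(
    series: DihedralSeries | np.ndarray,
    bin_width: float = 5.0,
) -> CircularHistogram:
    """Pooled normalised histogram of a circular angle series.

    ``bin_width`` (degrees) must divide 360.  Density integrates to 1 over
    the circle.  Per-replicate densities are attached when a
    :class:`DihedralSeries` is given.
    """
    if not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    if isinstance(series, DihedralSeries):
        reps = series.replicates
        pooled = series.pooled()
    else:
        pooled = np.asarray(series, dtype=float)
        reps = [pooled]
    if pooled.size == 0:
        raise ValueError("empty angle series")
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)

    def _hist(a: np.ndarray) -> np.ndarray:
        # (-180, 180]: shift exact -180 up to +180 before binning
        a = np.asarray(wrap_angle(a))
        counts, _ = np.histogram(np.where(a == -180.0, 180.0, a), bins=edges)
        # np.histogram puts 180.0 in the last bin (right edge inclusive): ok
        return counts / (a.size * bin_width)

    per_rep = [_hist(r) for r in reps if len(r)]
    density = _hist(pooled)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return CircularHistogram(
        bin_centers=centers,
        density=density,
        bin_width=bin_width,
        per_replicate=per_rep,
        n_samples=pooled.size,
    )


@dataclass(frozen=True)
class Peak:
    """One circular mode: interpolated center (degrees) and basin mass."""

    center: float
    mass: float
    height: float


def _circular_smooth(d: np.ndarray, window_bins: int) -> np.ndarray:
    if window_bins <= 1:
        return d.copy()
    kernel = np.ones(window_bins) / window_bins
    n = len(d)
    ext = np.r_[d[-window_bins:], d, d[:window_bins]]
    sm = np.convolve(ext, kernel, mode="same")
    return sm[window_bins : window_bins + n]


def detect_peaks(
    histogram: CircularHistogram,
    min_prominence_fraction: float = 0.05,
    smooth_deg: float = 15.0,
    min_height_factor: float = 1.5,
) -> list[Peak]:
    """Circularly-aware modes of a normalised histogram, sorted by mass.

    The density is first smoothed with a circular boxcar of ``smooth_deg``
    (an estimator choice that suppresses sampling noise; set 0 to disable).
    Local maxima are kept when their circular topographic prominence exceeds
    ``min_prominence_fraction`` of the global maximum *and* their smoothed
    height exceeds ``min_height_factor`` times the circular-uniform density
    1/360 — a structureless (uniform) series therefore yields no peaks, as
    its sampling fluctuations clear neither bar.  Each retained peak's
    mass is the integral of the *raw* density over its watershed basin
    (bounded by the minima between adjacent retained peaks), so masses sum
    to 1 whenever at least one peak is found.  Centers are refined by
    parabolic interpolation around the smoothed maximum.
    """
    from scipy.signal import find_peaks as _find_peaks

    d = np.asarray(histogram.density, dtype=float)
    n = len(d)
    w = max(1, int(round(smooth_deg / histogram.bin_width)))
    sm = _circular_smooth(d, w)
    if np.allclose(sm, sm[0]):
        return []
    tripled = np.r_[sm, sm, sm]
    idx, props = _find_peaks(tripled, prominence=0.0)
    keep = [(i - n, p) for i, p in zip(idx, props["prominences"]) if n <= i < 2 * n]
    threshold = min_prominence_fraction * sm.max()
    floor = min_height_factor / 360.0
    keep = [(i, p) for i, p in keep if p >= threshold and sm[i] >= floor]
    if not keep:
        return []
    keep.sort()
    centers_idx = [i for i, _ in keep]

    # watershed boundaries: minimum of smoothed density between adjacent peaks
    boundaries = []
    m = len(centers_idx)
    for a in range(m):
        i0 = centers_idx[a]
        i1 = centers_idx[(a + 1) % m]
        if m == 1:
            # single peak: boundary at global minimum opposite the peak
            j = int(np.argmin(np.r_[sm, sm][i0 : i0 + n])) + i0
            boundaries.append(j % n)
            break
        span = (i1 - i0) % n
        seg = [(i0 + k) % n for k in range(1, span)]
        if not seg:
            boundaries.append(i1 % n)
            continue
        j = min(seg, key=lambda k: sm[k])
        boundaries.append(j)

    peaks = []
    for a in range(m):
        i = centers_idx[a]
        left_b = boundaries[a - 1]
        right_b = boundaries[a] if m > 1 else boundaries[0]
        if m == 1:
            span = n
            basin = [(left_b + k) % n for k in range(n)]
        else:
            span = (right_b - left_b) % n or n
            basin = [(left_b + k) % n for k in range(span)]
        mass = float(np.sum(d[basin]) * histogram.bin_width)
        # parabolic sub-bin refinement on the smoothed density
        ym1, y0, yp1 = sm[(i - 1) % n], sm[i], sm[(i + 1) % n]
        denom = ym1 - 2 * y0 + yp1
        shift = 0.0 if abs(denom) < 1e-300 else 0.5 * (ym1 - yp1) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
        center = wrap_angle(histogram.bin_centers[i] + shift * histogram.bin_width)
        peaks.append(Peak(center=center, mass=mass, height=float(d[i])))
    peaks.sort(key=lambda p: -p.mass)
    return peaks


@dataclass
class RotamerStateAssignment:
    """Hard-core state labels per frame; UNASSIGNED (-1) outside every core."""

    labels: list[np.ndarray]
    centers: np.ndarray
    core_half_width: float
    dt_ps: float = 100.0


def assign_states(
    series: DihedralSeries,
    centers,
    core_half_width: float = 40.0,
) -> RotamerStateAssignment:
    """Assign each frame to the rotamer state whose core contains it.

    A frame belongs to state *k* iff its circular distance to ``centers[k]``
    is at most ``core_half_width``; otherwise it is UNASSIGNED (buffer zone).
    Cores must not overlap: centers pairwise separated by more than twice the
    half-width.
    """
    centers = np.asarray(wrap_angle(np.asarray(centers, dtype=float)), dtype=float).ravel()
    k = len(centers)
    for a in range(k):
        for b in range(a + 1, k):
            sep = abs(circular_difference(centers[a], centers[b]))
            if sep <= 2 * core_half_width:
                raise ValueError(
                    f"state cores overlap: centers {centers[a]:.1f} and {centers[b]:.1f} "
                    f"separated by {sep:.1f} <= 2*{core_half_width}"
                )
    labels = []
    for rep in series.replicates:
        dist = np.abs(circular_difference(rep[:, None], centers[None, :]))
        nearest = np.argmin(dist, axis=1)
        lab = np.where(dist[np.arange(len(rep)), nearest] <= core_half_width, nearest, UNASSIGNED)
        labels.append(lab.astype(int))
    return RotamerStateAssignment(
        labels=labels, centers=centers, core_half_width=core_half_width, dt_ps=series.dt_ps
    )


@dataclass
class RotationKinetics:
    """Hysteresis-filtered transition counts and dwell-time statistics."""

    n_events: int
    event_times_ns: list[list[float]]
    #: transition counts keyed by (from_state, to_state)
    transitions: dict[tuple[int, int], int]
    #: completed (uncensored) dwell durations per state, ns
    dwell_times_ns: dict[int, list[float]]
    #: censored edge dwells (first/last visit of each replicate), ns
    censored_dwells_ns: list[float]
    dt_ps: float
    symmetry_fold: int = 1
    #: for 3-fold symmetry: counts of +120° vs -120° transitions
    direction_counts: dict[str, int] = field(default_factory=dict)
    centers: np.ndarray | None = None

    @property
    def mean_dwell_ns(self) -> float:
        """Mean of completed dwells, pooled over states; NaN if none completed."""
        pool = [v for vs in self.dwell_times_ns.values() for v in vs]
        return float(np.mean(pool)) if pool else float("nan")

    def mean_dwell_per_state(self) -> dict[int, float]:
        return {
            s: (float(np.mean(v)) if v else float("nan"))
            for s, v in self.dwell_times_ns.items()
        }

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "event_times_ns": self.event_times_ns,
            "transitions": {f"{a}->{b}": c for (a, b), c in self.transitions.items()},
            "mean_dwell_ns": self.mean_dwell_ns,
            "mean_dwell_per_state_ns": {
                str(k): v for k, v in self.mean_dwell_per_state().items()
            },
            "n_censored_dwells": len(self.censored_dwells_ns),
            "symmetry_fold": self.symmetry_fold,
            "direction_counts": self.direction_counts,
        }


def rotation_events(
    assignment: RotamerStateAssignment,
    dt_ps: float | None = None,
    symmetry_fold: int = 1,
) -> RotationKinetics:
    """Count rotation events with core/buffer hysteresis and collect dwells.

    An event is registered only when a *different* state's core is entered;
    excursions into the UNASSIGNED buffer that return to the same core are
    not events.  Dwell = time between successive entries; the leading and
    trailing dwell of every replicate are censored (trajectory edge) and
    excluded from the mean.  For ``symmetry_fold=3`` transitions are also
    tallied by rotation direction (+120° vs -120°, by the circular ordering
    of the state centers).
    """
    dt_ns = (dt_ps if dt_ps is not None else assignment.dt_ps) / 1000.0
    total_assigned = sum(int(np.sum(lab != UNASSIGNED)) for lab in assignment.labels)
    if total_assigned == 0:
        raise ValueError("no assigned frames: cannot count rotation events")

    n_events = 0
    event_times: list[list[float]] = []
    transitions: dict[tuple[int, int], int] = {}
    dwells: dict[int, list[float]] = {int(s): [] for s in range(len(assignment.centers))}
    censored: list[float] = []
    direction = {"+120": 0, "-120": 0}

    for lab in assignment.labels:
        rep_events = []
        assigned_pos = np.flatnonzero(lab != UNASSIGNED)
        if len(assigned_pos) == 0:
            event_times.append(rep_events)
            continue
        cur = int(lab[assigned_pos[0]])
        entry = int(assigned_pos[0])
        first_visit = True
        for fi in assigned_pos[1:]:
            s = int(lab[fi])
            if s == cur:
                continue
            t_event = fi * dt_ns
            rep_events.append(t_event)
            n_events += 1
            transitions[(cur, s)] = transitions.get((cur, s), 0) + 1
            dwell = (fi - entry) * dt_ns
            if first_visit:
                censored.append(dwell)  # left-censored: entry not observed
                first_visit = False
            else:
                dwells[cur].append(dwell)
            if symmetry_fold == 3 and len(assignment.centers) == 3:
                step = circular_difference(
                    assignment.centers[s], assignment.centers[cur]
                )
                direction["+120" if step > 0 else "-120"] += 1
            cur = s
            entry = int(fi)
        # trailing dwell is right-censored; dwell = frames-in-state x dt
        censored.append((assigned_pos[-1] - entry + 1) * dt_ns)
        event_times.append(rep_events)

    return RotationKinetics(
        n_events=n_events,
        event_times_ns=event_times,
        transitions=transitions,
        dwell_times_ns=dwells,
        censored_dwells_ns=censored,
        dt_ps=dt_ps if dt_ps is not None else assignment.dt_ps,
        symmetry_fold=symmetry_fold,
        direction_counts=direction if symmetry_fold == 3 else {},
        centers=assignment.centers,
    )
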