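"""Ring-torsion time series, populations and two-state hopping statistics.

The terminal ionone rings of a xanthophyll can isomerise ("hopping
rotation") between two energy-minimum conformers of the ring torsion:
roughly 130 and -50 degrees for the epsilon ring (C5'-C6'-C7'-C8') and
-30/+30 degrees for the beta ring (C5-C6-C7-C8).  This module extracts the
torsion series, histograms the circular populations, assigns frames to
state windows, and counts dwell times and transitions.

All angular arithmetic is circular: differences are reduced into
(-180, 180] and state windows wrap around the branch cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classmap import AtomClassMap
from .core import Trajectory, dihedral_series

__all__ = [
    "TorsionSpec", "TorsionSeries", "TorsionState", "TorsionStateDef",
    "StateTrace", "EPS_RING_STATES", "BETA_RING_STATES",
    "EPS_RING_TORSION", "BETA_RING_TORSION",
    "extract_torsions", "torsion_histogram", "assign_states", "count_hopping",
    "wrap_angle",
]


def wrap_angle(a):
    """Reduce angles (degrees) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = a - 360.0 * np.round(a / 360.0)
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return float(w) if np.ndim(w) == 0 else w


@dataclass(frozen=True)
class TorsionSpec:
    """Named torsion defined by four atom names within one residue."""

    name: str
    atom_names: tuple[str, str, str, str]

    def __post_init__(self):
        if len(set(self.atom_names)) != 4:
            raise ValueError("torsion requires 4 distinct atoms")


# Ring torsions of the synthetic xanthophyll pseudo-topology (K-names) --
# the same specs with carotenoid names C5-C6-C7-C8 / C5'-C6'-C7'-C8' apply
# to real topologies.
BETA_RING_TORSION = TorsionSpec("beta_ring", ("K5", "K6", "K7", "K8"))
EPS_RING_TORSION = TorsionSpec("eps_ring", ("K5P", "K6P", "K7P", "K8P"))


@dataclass
class TorsionSeries:
    molecule_id: tuple[str, int]
    spec: TorsionSpec
    times: np.ndarray
    angles: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have equal length")


@dataclass(frozen=True)
class TorsionState:
    label: str
    center: float
    half_width: float

    def contains(self, angles) -> np.ndarray:
        return np.abs(wrap_angle(np.asarray(angles) - self.center)) <= self.half_width


@dataclass
class TorsionStateDef:
    """Two (or more) disjoint circular windows defining discrete states."""

    states: tuple[TorsionState, ...]

    def __post_init__(self):
        # pairwise disjointness on the circle
        for i, s in enumerate(self.states):
            for t in self.states[i + 1:]:
                gap = abs(wrap_angle(s.center - t.center))
                if gap < s.half_width + t.half_width:
                    raise ValueError(
                        f"state windows {s.label!r} and {t.label!r} overlap"
                    )


# Default windows cover the observed oscillation bands around each minimum.
EPS_RING_STATES = TorsionStateDef(
    (TorsionState("E130", 130.0, 40.0), TorsionState("E50", -50.0, 40.0))
)
BETA_RING_STATES = TorsionStateDef(
    (TorsionState("B30", 30.0, 25.0), TorsionState("Bm30", -30.0, 25.0))
)

UNASSIGNED = "unassigned"


def extract_torsions(
    traj: Trajectory, spec: TorsionSpec, classmap: AtomClassMap
) -> list[TorsionSeries]:
    """One torsion-angle series per xanthophyll molecule."""
    by_res: dict[tuple[str, int], dict[str, int]] = {}
    for a in traj.topology:
        by_res.setdefault((a.residue_name, a.residue_id), {})[a.name] = a.index
    coords = traj.coords
    times = traj.times
    out = []
    for mol in classmap.xan_residues():
        names = by_res.get(mol, {})
        try:
            idx = [names[n] for n in spec.atom_names]
        except KeyError as missing:
            raise ClassMapMissingAtom(
                f"molecule {mol} lacks torsion atom {missing} for {spec.name!r}"
            ) from None
        out.append(TorsionSeries(mol, spec, times, dihedral_series(coords, idx)))
    if not out:
        raise ClassMapMissingAtom("no xanthophyll molecules found in topology")
    return out


class ClassMapMissingAtom(KeyError):
    """A torsion spec references atoms absent from a molecule."""


def torsion_histogram(series: TorsionSeries | np.ndarray, bin_width: float = 5.0):
    """Normalised circular population density over (-180, 180].

    Returns (bin_centers, density) with sum(density) * bin_width == 1.
    """
    angles = series.angles if isinstance(series, TorsionSeries) else np.asarray(series)
    if angles.size == 0:
        raise ValueError("empty angle series")
    if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    # shift the branch-cut sample 180 -> -180 bin is equivalent on the circle
    a = np.where(angles > 180.0 - 1e-12, angles - 360.0, wrap_angle(angles))
    counts, _ = np.histogram(a, bins=edges)
    density = counts / (angles.size * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


@dataclass
class StateTrace:
    """Per-frame state labels with transition and dwell bookkeeping."""

    molecule_id: tuple[str, int]
    times: np.ndarray
    labels: np.ndarray  # object array of state labels / UNASSIGNED
    transitions: list[tuple[float, str, str]] = field(default_factory=list)
    dwells: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


def assign_states(
    series: TorsionSeries, states: TorsionStateDef, min_dwell: float = 0.0
) -> StateTrace:
    """Label frames by state window and record inter-state transitions.

    A frame outside every window is ``unassigned`` and transparent for
    transition counting (the previous state carries through).  A change of
    state is recorded as a transition only when the new state persists for
    at least ``min_dwell`` ps; shorter excursions are filtered out and do
    not interrupt the surrounding dwell.
    """
    labels = np.full(series.angles.shape, UNASSIGNED, dtype=object)
    for st in states.states:
        labels[st.contains(series.angles)] = st.label

    times = series.times
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0

    # Collapse into runs of assigned states (unassigned is transparent).
    runs: list[list] = []  # [label, start_time, end_time]
    for t, lab in zip(times, labels):
        if lab == UNASSIGNED:
            continue
        if runs and runs[-1][0] == lab:
            runs[-1][2] = t
        else:
            runs.append([lab, t, t])

    # Filter excursions shorter than min_dwell: merge them away.
    accepted: list[list] = []
    for lab, t0, t1 in runs:
        duration = t1 - t0 + dt
        if accepted and accepted[-1][0] == lab:
            accepted[-1][2] = t1
            continue
        if duration < min_dwell:
            continue
        accepted.append([lab, t0, t1])
    # merging may have made neighbours equal; recompress
    merged: list[list] = []
    for run in accepted:
        if merged and merged[-1][0] == run[0]:
            merged[-1][2] = run[2]
        else:
            merged.append(list(run))

    transitions = [
        (merged[i + 1][1], merged[i][0], merged[i + 1][0])
        for i in range(len(merged) - 1)
    ]
    dwells = [(lab, t1 - t0 + dt) for lab, t0, t1 in merged]
    return StateTrace(series.molecule_id, times, labels, transitions, dwells)


def count_hopping(traces: Sequence[StateTrace]) -> pd.DataFrame:
    """Per-molecule transition counts, rates per microsecond and dwell stats.

    Zero-transition traces are reported as such (rate 0).
    """
    if not traces:
        raise ValueError("need at least one state trace")
    rows = []
    for tr in traces:
        span_ps = float(tr.times[-1] - tr.times[0]) if tr.times.size > 1 else 0.0
        rate = tr.n_transitions / (span_ps / 1e6) if span_ps > 0 else 0.0
        dwell_arr = np.array([d for _, d in tr.dwells]) if tr.dwells else np.array([])
        rows.append(
            {
                "molecule": f"{tr.molecule_id[0]}:{tr.molecule_id[1]}",
                "n_transitions": tr.n_transitions,
                "span_ps": span_ps,
                "rate_per_us": rate,
                "mean_dwell_ps": float(dwell_arr.mean()) if dwell_arr.size else np.nan,
                "max_dwell_ps": float(dwell_arr.max()) if dwell_arr.size else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    pooled = {
        "molecule": "pooled",
        "n_transitions": int(df["n_transitions"].sum()),
        "span_ps": float(df["span_ps"].sum()),
        "rate_per_us": float(df["n_transitions"].sum() / (df["span_ps"].sum() / 1e6))
        if df["span_ps"].sum() > 0
        else 0.0,
        "mean_dwell_ps": float(np.nanmean(df["mean_dwell_ps"]))
        if df["mean_dwell_ps"].notna().any()
        else np.nan,
        "max_dwell_ps": float(np.nanmax(df["max_dwell_ps"]))
        if df["max_dwell_ps"].notna().any()
        else np.nan,
    }
    return pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)
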