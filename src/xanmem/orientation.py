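"""Xanthophyll orientation in the bilayer: ring-COM z trajectories against
leaflet interface references, horizontal/vertical classification with
reorientation-event timing, polyene-plane (beta-up/beta-down) assignment,
long-axis rotation angle theta, molecular length, hydrophobic width and
aggregation monitoring.

Conventions
-----------
A molecule is *vertical* (transmembrane) when its two ring centres of mass
sit in opposite interfacial slabs, *horizontal* when both sit in the same
leaflet's slab, and *transit* otherwise.  The interfacial slab of a leaflet
is the z band between that leaflet's mean glycerol-O and mean P planes,
padded by ``tol`` (default 2 A).  Frame-level flicker is suppressed by a
running-majority filter; a reorientation event is a maximal transit run
bounded by two different stable labels, and its time is the start of the
new stable label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classmap import AtomClassMap, ClassMapError
from .core import Trajectory, center_of_mass, min_image_displacement

__all__ = [
    "InterfaceRef", "OrientationSeries", "RotationSeries",
    "interface_reference", "ring_z_series", "classify_orientation",
    "orientation_series", "plane_orientation", "theta_rotation",
    "molecular_length", "hydrophobic_width", "check_aggregation",
]

H, V, TRANSIT = "H", "V", "transit"


@dataclass
class InterfaceRef:
    """Per-frame interface reference z values (A), one entry per frame."""

    times: np.ndarray
    p_upper: np.ndarray
    p_lower: np.ndarray
    og_upper: np.ndarray
    og_lower: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        ok = (
            np.all(self.p_upper > self.og_upper)
            and np.all(self.og_upper > self.center)
            and np.all(self.center > self.og_lower)
            and np.all(self.og_lower > self.p_lower)
        )
        if not ok:
            raise ValueError(
                "interface ordering violated: expect P_up > Og_up > center > Og_low > P_low"
            )


def interface_reference(traj: Trajectory, classmap: AtomClassMap) -> InterfaceRef:
    """Mean P and glycerol-O z per leaflet per frame, plus bilayer centre.

    Leaflets are assigned per frame by the sign of z minus the bilayer
    centre (midpoint of the two leaflet P means, seeded by the global P
    mean).
    """
    p_sel = classmap.require("P")
    og_sel = classmap.require("glycerol_O")
    coords = traj.coords
    zp = coords[:, p_sel, 2]
    zog = coords[:, og_sel, 2]

    seed = zp.mean(axis=1, keepdims=True)
    up = zp > seed
    if not (0 < up[0].sum() < zp.shape[1]):
        raise ClassMapError("one leaflet is empty: cannot build interface reference")
    p_upper = np.array([zp[i, up[i]].mean() for i in range(len(zp))])
    p_lower = np.array([zp[i, ~up[i]].mean() for i in range(len(zp))])
    center = 0.5 * (p_upper + p_lower)
    og_up = zog > center[:, None]
    og_upper = np.array([zog[i, og_up[i]].mean() for i in range(len(zog))])
    og_lower = np.array([zog[i, ~og_up[i]].mean() for i in range(len(zog))])
    return InterfaceRef(traj.times, p_upper, p_lower, og_upper, og_lower, center)


def ring_z_series(traj: Trajectory, classmap: AtomClassMap):
    """Per-molecule (z_beta, z_eps) ring-COM z trajectories (mass-weighted)."""
    beta = classmap.per_residue("ring_beta_atoms")
    eps = classmap.per_residue("ring_eps_atoms")
    out = {}
    for mol in classmap.xan_residues():
        if mol not in beta or mol not in eps:
            raise ClassMapError(f"molecule {mol} lacks ring-atom selections")
        zb = center_of_mass(traj, beta[mol])[:, 2]
        ze = center_of_mass(traj, eps[mol])[:, 2]
        out[mol] = (zb, ze)
    return out


@dataclass
class OrientationSeries:
    molecule_id: tuple[str, int]
    times: np.ndarray
    z_beta: np.ndarray
    z_eps: np.ndarray
    labels: np.ndarray  # smoothed per-frame labels: H / V / transit
    raw_labels: np.ndarray
    events: list[tuple[float, float, str]] = field(default_factory=list)
    # events: (start_ps, end_ps, direction) e.g. (t0, t1, "H->V")


def _majority_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return labels.copy()
    window = min(window, len(labels))
    if window % 2 == 0:
        window += 1 if window < len(labels) else -1
    if window <= 1:
        return labels.copy()
    kernel = np.ones(window)
    counts = []
    cats = [H, V, TRANSIT]
    for cat in cats:
        b = (labels == cat).astype(float)
        # same-mode convolution counts occurrences in the centred window
        counts.append(np.convolve(b, kernel, mode="same"))
    counts = np.stack(counts)
    return np.array([cats[i] for i in counts.argmax(axis=0)], dtype=object)


def classify_orientation(
    z_beta: np.ndarray,
    z_eps: np.ndarray,
    ref: InterfaceRef,
    smoothing: float = 1000.0,
    tol: float = 2.0,
    molecule_id: tuple[str, int] = ("XAN", 0),
) -> OrientationSeries:
    """Label each frame H/V/transit and extract reorientation events.

    ``smoothing`` (ps) sets both the running-majority window and the
    minimum persistence for a label to count as stable.
    """
    times = ref.times
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0

    up_lo, up_hi = ref.og_upper - tol, ref.p_upper + tol
    lo_lo, lo_hi = ref.p_lower - tol, ref.og_lower + tol

    def in_upper(z):
        return (z >= up_lo) & (z <= up_hi)

    def in_lower(z):
        return (z >= lo_lo) & (z <= lo_hi)

    bu, bl = in_upper(z_beta), in_lower(z_beta)
    eu, el = in_upper(z_eps), in_lower(z_eps)
    raw = np.full(times.shape, TRANSIT, dtype=object)
    raw[(bu & el) | (bl & eu)] = V
    raw[(bu & eu) | (bl & el)] = H

    window = max(1, int(round(smoothing / dt)))
    labels = _majority_smooth(raw, window)

    # stable runs of H/V with persistence >= smoothing
    runs = []  # (label, i0, i1) inclusive frame indices
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j + 1
    stable = [
        (lab, i0, i1)
        for lab, i0, i1 in runs
        if lab in (H, V) and (times[i1] - times[i0] + dt) >= smoothing
    ]
    events = []
    for (lab_a, _, i1a), (lab_b, i0b, _) in zip(stable, stable[1:]):
        if lab_a != lab_b:
            events.append((float(times[i1a]), float(times[i0b]), f"{lab_a}->{lab_b}"))
    return OrientationSeries(molecule_id, times, z_beta, z_eps, labels, raw, events)


def orientation_series(
    traj: Trajectory,
    classmap: AtomClassMap,
    smoothing: float = 1000.0,
    tol: float = 2.0,
    ref: InterfaceRef | None = None,
) -> dict[tuple[str, int], OrientationSeries]:
    """Classify every xanthophyll molecule of a trajectory."""
    if ref is None:
        ref = interface_reference(traj, classmap)
    out = {}
    for mol, (zb, ze) in ring_z_series(traj, classmap).items():
        out[mol] = classify_orientation(zb, ze, ref, smoothing, tol, molecule_id=mol)
    return out


def plane_orientation(
    traj: Trajectory,
    classmap: AtomClassMap,
    orientation: OrientationSeries,
    ref: InterfaceRef | None = None,
) -> str:
    """beta_up / beta_down polyene-plane label for a horizontal molecule.

    beta_up means the beta-half methyls (hence the beta-ring OH) point
    towards the water phase of the leaflet hosting the molecule.  Defined
    only over stable-H frames; raises if the molecule is never horizontal.
    """
    mol = orientation.molecule_id
    mask = orientation.labels == H
    if not mask.any():
        raise ValueError(f"molecule {mol} has no horizontal frames")
    if ref is None:
        ref = interface_reference(traj, classmap)
    met_b = classmap.per_residue("met_beta").get(mol)
    met_e = classmap.per_residue("met_eps").get(mol)
    if met_b is None or met_e is None:
        raise ClassMapError(f"molecule {mol} lacks MET selections")
    z_mb = center_of_mass(traj, met_b)[:, 2][mask]
    z_me = center_of_mass(traj, met_e)[:, 2][mask]
    mol_z = 0.5 * (orientation.z_beta + orientation.z_eps)[mask]
    upper = mol_z > ref.center[mask]
    beta_up_frames = (z_mb > z_me) == upper
    frac = beta_up_frames.mean()
    return "beta_up" if frac >= 0.5 else "beta_down"


@dataclass
class RotationSeries:
    molecule_id: tuple[str, int]
    times: np.ndarray
    theta: np.ndarray  # degrees in [0, 360); NaN where undefined
    theta_unwrapped: np.ndarray


def theta_rotation(
    traj: Trajectory,
    classmap: AtomClassMap,
    orientation: OrientationSeries,
    stride: float = 100.0,
) -> RotationSeries:
    """Long-axis rotation angle theta of the MET-C13 bond, sampled every
    ``stride`` ps.

    Vertical molecules: angle between the bond's x-y projection and the
    x axis.  Horizontal molecules: angle from the z axis within the
    vertical plane perpendicular to the long molecular axis (the plane the
    bond sweeps when the molecule rolls).  The unwrapped series accumulates
    nearest-image angular steps.
    """
    mol = orientation.molecule_id
    met = classmap.per_residue("met_c13").get(mol)
    c13 = classmap.per_residue("C13").get(mol)
    c3 = classmap.per_residue("C3").get(mol)
    c3p = classmap.per_residue("C3prime").get(mol)
    if met is None or c13 is None or c3 is None or c3p is None:
        raise ClassMapError(f"molecule {mol} lacks MET/C13/C3 selections")
    times = traj.times
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    step = max(1, int(round(stride / dt)))
    sample = np.arange(0, len(times), step)

    coords = traj.coords
    v = coords[sample, c13[0]] - coords[sample, met[0]]
    axis = coords[sample, c3p[0]] - coords[sample, c3[0]]
    labels = orientation.labels[sample]

    theta = np.full(len(sample), np.nan)
    for k in range(len(sample)):
        if labels[k] == H:
            u = axis[k] / np.linalg.norm(axis[k])
            e1 = np.array([0.0, 0.0, 1.0]) - u[2] * u
            n1 = np.linalg.norm(e1)
            if n1 < 1e-9:
                continue  # axis vertical while labelled H: undefined sample
            e1 /= n1
            e2 = np.cross(u, e1)
            proj = np.array([np.dot(v[k], e1), np.dot(v[k], e2)])
            if np.linalg.norm(proj) < 1e-9:
                continue
            theta[k] = np.degrees(np.arctan2(proj[1], proj[0])) % 360.0
        else:
            if np.hypot(v[k, 0], v[k, 1]) < 1e-9:
                continue  # zero-length x-y projection: sample missing
            theta[k] = np.degrees(np.arctan2(v[k, 1], v[k, 0])) % 360.0

    unwrapped = np.full_like(theta, np.nan)
    prev = None
    acc = 0.0
    for k, th in enumerate(theta):
        if np.isnan(th):
            continue
        if prev is None:
            acc = th
        else:
            d = th - prev
            d -= 360.0 * np.round(d / 360.0)
            acc += d
        unwrapped[k] = acc
        prev = th
    return RotationSeries(mol, times[sample], theta, unwrapped)


def molecular_length(traj: Trajectory, classmap: AtomClassMap) -> pd.DataFrame:
    """Per-frame C3-C3' distance (A) per molecule, with mean and sd."""
    c3 = classmap.per_residue("C3")
    c3p = classmap.per_residue("C3prime")
    rows = []
    coords = traj.coords
    for mol in classmap.xan_residues():
        if mol not in c3 or mol not in c3p:
            raise ClassMapError(f"molecule {mol} lacks C3/C3' atoms")
        d = np.linalg.norm(
            np.stack(
                [
                    min_image_displacement(
                        coords[i, c3[mol][0]], coords[i, c3p[mol][0]], traj.frames[i].box
                    )
                    for i in range(traj.n_frames)
                ]
            ),
            axis=-1,
        )
        rows.append(
            {
                "molecule": f"{mol[0]}:{mol[1]}",
                "mean_A": float(d.mean()),
                "sd_A": float(d.std(ddof=0)),
                "series": d,
            }
        )
    return pd.DataFrame(rows)


def hydrophobic_width(
    traj: Trajectory, classmap: AtomClassMap, role: str = "Oc"
) -> tuple[np.ndarray, float, float]:
    """Distance between the leaflet mean z planes of ``role`` atoms
    (default carbonyl oxygens Oc), per frame, with mean and sd (A)."""
    sel = classmap.require(role)
    ref_p = classmap.require("P")
    coords = traj.coords
    center = np.array(
        [
            0.5
            * (
                coords[i, ref_p, 2][coords[i, ref_p, 2] > coords[i, ref_p, 2].mean()].mean()
                + coords[i, ref_p, 2][coords[i, ref_p, 2] <= coords[i, ref_p, 2].mean()].mean()
            )
            for i in range(traj.n_frames)
        ]
    )
    z = coords[:, sel, 2]
    width = np.array(
        [
            z[i][z[i] > center[i]].mean() - z[i][z[i] <= center[i]].mean()
            for i in range(traj.n_frames)
        ]
    )
    return width, float(width.mean()), float(width.std(ddof=0))


def check_aggregation(
    traj: Trajectory,
    classmap: AtomClassMap,
    cutoff: float = 4.0,
    min_frames: int = 5,
) -> list[dict]:
    """Episodes of sustained close contact between xanthophyll molecules.

    An episode is >= ``min_frames`` consecutive frames in which the minimum
    heavy-atom/heavy-atom distance between two molecules is below
    ``cutoff``.  An empty list means no (even temporary) dimers.
    """
    heavy = classmap.per_residue("xan_heavy")
    mols = classmap.xan_residues()
    if len(mols) < 2:
        raise ValueError("need at least two xanthophyll molecules")
    coords = traj.coords
    episodes = []
    for ai in range(len(mols)):
        for bi in range(ai + 1, len(mols)):
            a, b = mols[ai], mols[bi]
            ia, ib = heavy[a], heavy[b]
            close = np.empty(traj.n_frames, dtype=bool)
            for i in range(traj.n_frames):
                disp = min_image_displacement(
                    coords[i, ia][:, None, :], coords[i, ib][None, :, :],
                    traj.frames[i].box,
                )
                close[i] = np.min(np.linalg.norm(disp, axis=-1)) < cutoff
            i = 0
            while i < len(close):
                if close[i]:
                    j = i
                    while j + 1 < len(close) and close[j + 1]:
                        j += 1
                    if j - i + 1 >= min_frames:
                        episodes.append(
                            {
                                "pair": (f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}"),
                                "start_ps": float(traj.times[i]),
                                "end_ps": float(traj.times[j]),
                                "n_frames": j - i + 1,
                            }
                        )
                    i = j + 1
                else:
                    i += 1
    return episodes
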