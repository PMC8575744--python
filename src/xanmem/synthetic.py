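"""Ground-truth synthetic bilayer trajectories.

Builds slab "trajectories" with the reference composition (188 POPC,
6 xanthophylls, ~8,500 waters) in which every quantity the analysis
stages estimate is *prescribed*: ring-torsion two-state kinetics,
orientation schedules with interpolated horizontal-to-vertical flips,
polyene-plane labels, long-axis rotational diffusion, and per-partner
bonding telegraph processes realised as exact H-bond geometry.  This is a
statistical-structure emulator, not an MD substitute: lipids are
leaflet-anchored pseudo-molecules jittered about their reference planes,
and density realism is explicitly not a goal.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .contacts import Bond, BondEventMatrix
from .core import Atom, Frame, Trajectory
from .lifetime import DecayCurve
from .presets import COMPOSITION, GEOMETRY

__all__ = [
    "TelegraphSpec", "TorsionTruth", "XanSpec", "SyntheticTruth",
    "default_truth", "generate", "generate_event_matrix",
    "generate_decay_curve", "simulate_telegraph", "place_dihedral",
]


# --------------------------------------------------------------------------
# truth specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state (on/off) Markov process with rates in 1/ps."""

    k_on: float = 0.0   # off -> on
    k_off: float = 0.0  # on -> off

    def __post_init__(self):
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("telegraph rates must be non-negative")

    @property
    def p_on(self) -> float:
        k = self.k_on + self.k_off
        return self.k_on / k if k > 0 else 0.0

    @property
    def relaxation_rate(self) -> float:
        return self.k_on + self.k_off


@dataclass(frozen=True)
class TorsionTruth:
    """Two-state ring-torsion kinetics: state centres (deg), angular noise
    sigma (deg), and transition rates between state 0 and state 1 (1/ps)."""

    centers: tuple[float, float]
    sigma: float
    k01: float
    k10: float
    start_state: int | None = None  # None = draw from stationary distribution

    @property
    def p1(self) -> float:
        k = self.k01 + self.k10
        return self.k01 / k if k > 0 else 0.0


@dataclass(frozen=True)
class XanSpec:
    """Placement schedule for one xanthophyll molecule."""

    initial: str = "V"                  # 'H' or 'V'
    leaflet: int = 1                    # +1 upper / -1 lower (H molecules)
    beta_end: str = "up"                # which end is up for V molecules
    plane_label: str = "beta_up"        # polyene-plane label while horizontal
    flip_time: float | None = None      # ps; END of the H->V transit
    azimuth: float = 0.0                # degrees, long-axis direction while H
    center_xy: tuple[float, float] = (40.0, 40.0)


@dataclass
class SyntheticTruth:
    """Full prescription of one synthetic system."""

    n_popc: int = COMPOSITION["n_popc"]
    n_xan: int = COMPOSITION["n_xan"]
    n_water: int = COMPOSITION["n_water"]
    box: tuple[float, float, float] = GEOMETRY["box"]
    p_plane: float = GEOMETRY["p_plane"]
    og_plane: float = GEOMETRY["og_plane"]
    oc_plane: float = GEOMETRY["oc_plane"]
    rod_length: float = GEOMETRY["rod_length"]
    lipid_sigma_z: float = 0.5
    lipid_sigma_xy: float = 1.0
    xan_jitter: float = 0.3             # rigid-body translational jitter, A
    transit_duration: float = 20000.0   # ps over which a flip interpolates
    xan: tuple[XanSpec, ...] = ()
    eps_torsion: TorsionTruth = TorsionTruth((130.0, -50.0), 10.0, 0.0, 0.0, 0)
    beta_torsion: TorsionTruth = TorsionTruth((30.0, -30.0), 8.0, 0.001, 0.002)
    water_slots: int = 2
    water_telegraph: TelegraphSpec = TelegraphSpec(0.00929, 0.005)    # p=0.65
    op_telegraph: TelegraphSpec = TelegraphSpec(0.001364, 0.01)       # p=0.12
    bridge_telegraph: TelegraphSpec = TelegraphSpec(0.002463, 0.005)  # p=0.33
    charge_telegraph: TelegraphSpec = TelegraphSpec(0.00933, 0.004)   # p=0.70
    theta_diffusion: float = 0.06       # deg^2/ps for vertical molecules
    seed: int = 0

    def __post_init__(self):
        if min(self.n_popc, self.n_xan, self.n_water) <= 0:
            raise ValueError("composition counts must be positive")
        if self.rod_length + 10.0 > min(self.box):
            raise ValueError("rod (plus bonding shell) does not fit in the box")
        if not self.xan:
            self.xan = tuple(_default_xan_specs(self.n_xan))
        if len(self.xan) != self.n_xan:
            raise ValueError("need one XanSpec per xanthophyll")

    def expected_means(self) -> dict:
        """Stationary per-OH mean counts implied by the telegraphs."""
        return {
            "water": self.water_slots * self.water_telegraph.p_on
            + self.bridge_telegraph.p_on,
            "Op": self.op_telegraph.p_on,
            "bridge": self.bridge_telegraph.p_on,
            "choline": self.charge_telegraph.p_on,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["expected_means"] = self.expected_means()
        return d


# xy placement sites chosen so vertical columns and horizontal rods (all
# horizontal molecules run along x) stay > 10 A apart, including the 6 A
# bonding-partner shell
_XY_SITES = [(12.0, 12.0), (12.0, 68.0), (48.0, 12.0), (48.0, 68.0),
             (48.0, 40.0), (48.0, 26.0), (70.0, 54.0), (30.0, 40.0)]


def _default_xan_specs(n: int) -> list[XanSpec]:
    base = [
        XanSpec(initial="V", beta_end="up", center_xy=_XY_SITES[0]),
        XanSpec(initial="V", beta_end="down", center_xy=_XY_SITES[1]),
        XanSpec(initial="H", leaflet=1, plane_label="beta_up",
                azimuth=0.0, center_xy=_XY_SITES[2]),
        XanSpec(initial="H", leaflet=-1, plane_label="beta_down",
                azimuth=0.0, center_xy=_XY_SITES[3]),
        XanSpec(initial="H", leaflet=1, plane_label="beta_down",
                azimuth=0.0, center_xy=_XY_SITES[4]),
        XanSpec(initial="H", leaflet=-1, plane_label="beta_up",
                azimuth=0.0, center_xy=_XY_SITES[5]),
    ]
    out = [base[i % len(base)] for i in range(n)]
    for i in range(len(base), n):
        out[i] = XanSpec(
            initial=out[i].initial, leaflet=out[i].leaflet,
            beta_end=out[i].beta_end, plane_label=out[i].plane_label,
            flip_time=out[i].flip_time, azimuth=out[i].azimuth,
            center_xy=_XY_SITES[i % len(_XY_SITES)],
        )
    return out


def default_truth(duration: float, seed: int = 0, flip_fraction: float = 0.45,
                  **overrides) -> SyntheticTruth:
    """Reference truth: two vertical molecules, four horizontal of which the
    last two flip to vertical at ``flip_fraction * duration``."""
    specs = _default_xan_specs(overrides.pop("n_xan", COMPOSITION["n_xan"]))
    flip = flip_fraction * duration
    for i in (4, 5):
        if i < len(specs):
            specs[i] = XanSpec(
                initial="H", leaflet=specs[i].leaflet,
                plane_label=specs[i].plane_label, flip_time=flip,
                azimuth=specs[i].azimuth, center_xy=specs[i].center_xy,
            )
    return SyntheticTruth(n_xan=len(specs), xan=tuple(specs), seed=seed, **overrides)


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------


def simulate_telegraph(
    rng: np.random.Generator,
    n_series: int,
    n_steps: int,
    dt: float,
    spec: TelegraphSpec,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Exact-in-distribution sampling of on/off telegraph states on a grid."""
    k = spec.relaxation_rate
    p = spec.p_on
    decay = math.exp(-k * dt) if k > 0 else 1.0
    p_on_given_on = p + (1 - p) * decay
    p_on_given_off = p * (1 - decay)
    out = np.empty((n_series, n_steps), dtype=bool)
    if start is None:
        state = rng.random(n_series) < p
    else:
        state = np.asarray(start, dtype=bool).copy()
    out[:, 0] = state
    for t in range(1, n_steps):
        u = rng.random(n_series)
        state = np.where(state, u < p_on_given_on, u < p_on_given_off)
        out[:, t] = state
    return out


def _markov_angles(rng, n_steps, dt, truth: TorsionTruth) -> tuple[np.ndarray, np.ndarray]:
    spec = TelegraphSpec(truth.k01, truth.k10)  # state 1 = "on"
    start = None
    if truth.start_state is not None:
        start = np.array([bool(truth.start_state)])
    states = simulate_telegraph(rng, 1, n_steps, dt, spec, start=start)[0]
    centers = np.where(states, truth.centers[1], truth.centers[0])
    angles = centers + rng.normal(0.0, truth.sigma, size=n_steps)
    return angles, states.astype(int)


def place_dihedral(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom D so that dihedral(a, b, c, D) == torsion.

    ``angle`` is the b-c-D bond angle and ``torsion`` the a-b-c-D dihedral,
    both in degrees (IUPAC sign convention).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear a, b, c: torsion undefined")
    n /= nn
    m = np.cross(n, bc)
    th = math.radians(angle)
    ph = math.radians(torsion)
    d_local = np.array(
        [-bond * math.cos(th), bond * math.sin(th) * math.cos(ph),
         bond * math.sin(th) * math.sin(ph)]
    )
    return c + bc * d_local[0] + m * d_local[1] + n * d_local[2]


def _rotation(azimuth_deg: float, tilt_deg: float, roll_deg: float) -> np.ndarray:
    """R = Rz(azimuth) @ Ry(tilt) @ Rx(roll); body x is the long axis."""
    ca, sa = math.cos(math.radians(azimuth_deg)), math.sin(math.radians(azimuth_deg))
    ct, st = math.cos(math.radians(tilt_deg)), math.sin(math.radians(tilt_deg))
    cr, sr = math.cos(math.radians(roll_deg)), math.sin(math.radians(roll_deg))
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry = np.array([[ct, 0, st], [0, 1.0, 0], [-st, 0, ct]])
    rx = np.array([[1.0, 0, 0], [0, cr, -sr], [0, sr, cr]])
    return rz @ ry @ rx


# --------------------------------------------------------------------------
# topology assembly
# --------------------------------------------------------------------------

# lipid pseudo-atom z planes as (name, |z|, xy offset) -- z is multiplied by
# the leaflet sign
_LIPID_LAYOUT = [
    ("N", 23.0, (0.5, 0.0)),
    ("C13", 23.5, (1.5, 0.5)), ("C14", 23.5, (-0.5, 1.2)), ("C15", 23.5, (0.0, -1.3)),
    ("P", 20.0, (0.0, 0.0)),
    ("O13", 20.5, (1.2, 0.4)), ("O14", 20.5, (-1.2, -0.4)),
    ("O11", 19.5, (0.8, -0.8)), ("O12", 19.5, (-0.8, 0.8)),
    ("O21", 15.0, (0.7, 0.7)), ("O31", 15.0, (-0.7, -0.7)),
    ("O22", 15.15, (1.3, -0.3)), ("O32", 15.15, (-1.3, 0.3)),
    ("CA1", 10.0, (0.6, 0.0)), ("CA2", 6.0, (-0.6, 0.0)),
]


def _xan_body(D: float) -> tuple[list[str], np.ndarray, dict]:
    """Body-frame pseudo-atom layout of a rigid xanthophyll rod.

    The two ring hexagons lie perpendicular to the long axis with centres
    at the rod ends, so each ring's centre of mass coincides with the end
    of the C3-C3' segment; C3/C3' are matching hexagon vertices, which
    keeps their distance exactly ``D`` (the apparent molecular length).
    """
    r = 1.4
    hexa = {
        "K3": (0.0, r), "K2": (r * 0.866, r * 0.5), "K4": (-r * 0.866, r * 0.5),
        "K5": (-r * 0.866, -r * 0.5), "K6": (0.0, -r), "K1": (r * 0.866, -r * 0.5),
    }
    names, pos = [], []

    def add(name, s, v, w):
        names.append(name)
        pos.append((s, v, w))

    for k, (v, w) in hexa.items():
        add(k, 0.0, v, w)
    add("K7", 1.5, 0.0, 0.0)
    add("K8", 0.0, 0.0, 0.0)  # placeholder: torsion-dependent
    add("OB", -1.4, 0.0, 1.4)
    add("HB", -2.36, 0.0, 1.4)
    for j, f in enumerate((0.25, 0.375, 0.625, 0.75), start=1):
        add(f"KP{j}", f * D, 0.0, 0.0)
    add("K13", 0.4 * D, 0.0, 0.0)
    add("MB1", 0.3 * D, 1.5, 0.0)
    add("MB2", 0.4 * D, 1.5, 0.0)
    add("ME1", 0.7 * D, -1.5, 0.0)
    add("ME2", 0.6 * D, -1.5, 0.0)
    for k, (v, w) in hexa.items():
        add(k + "P", D, v, w)
    add("K7P", D - 1.5, 0.0, 0.0)
    add("K8P", 0.0, 0.0, 0.0)  # placeholder
    add("OE", D + 1.4, 0.0, 1.4)
    add("HE", D + 2.36, 0.0, 1.4)
    idx = {n: i for i, n in enumerate(names)}
    return names, np.array(pos, dtype=float), idx


def _torsion_sign(body: np.ndarray, idx: dict, primed: bool) -> float:
    """Calibrate the sign convention of the NeRF placement against the
    analysis dihedral for this ring's atom geometry."""
    from .core import dihedral

    suff = "P" if primed else ""
    a, b, c = (body[idx["K5" + suff]], body[idx["K6" + suff]], body[idx["K7" + suff]])
    d = place_dihedral(a, b, c, 1.5, 120.0, 47.0)
    meas = dihedral(a, b, c, d)
    return 1.0 if abs(meas - 47.0) < 1e-6 else -1.0


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------


def generate(
    truth: SyntheticTruth, duration: float, spacing: float = 1.0
) -> tuple[Trajectory, SyntheticTruth]:
    """Build the synthetic trajectory prescribed by ``truth``.

    ``duration`` and ``spacing`` in ps; frame count is
    ``round(duration / spacing) + 1``.  Deterministic given ``truth.seed``.
    """
    if duration < spacing:
        raise ValueError("duration must cover at least one frame interval")
    rng = np.random.default_rng(truth.seed)
    n_frames = int(round(duration / spacing)) + 1
    times = np.arange(n_frames) * spacing
    box = np.asarray(truth.box, dtype=float)
    D = truth.rod_length

    atoms: list[Atom] = []
    resid = 0

    # ---- lipids (regular grid, two leaflets) ------------------------------
    n_per_leaf = truth.n_popc // 2
    extra = truth.n_popc - 2 * n_per_leaf
    sites = []
    for leaf_i, count in enumerate((n_per_leaf + extra, n_per_leaf)):
        sign = 1 if leaf_i == 0 else -1
        nx = int(np.ceil(np.sqrt(count)))
        spacing_xy = box[0] / nx
        k = 0
        for gy in range(nx):
            for gx in range(nx):
                if k >= count:
                    break
                sites.append((sign, (gx + 0.5) * spacing_xy, (gy + 0.5) * spacing_xy))
                k += 1
    lipid_atom_index: list[list[int]] = []
    for sign, sx, sy in sites:
        resid += 1
        rows = []
        for name, zmag, (ox, oy) in _LIPID_LAYOUT:
            rows.append(len(atoms))
            atoms.append(Atom(len(atoms), name, "POPC", resid))
        lipid_atom_index.append(rows)
    lipid_base = np.zeros((len(sites), len(_LIPID_LAYOUT), 3))
    for li, (sign, sx, sy) in enumerate(sites):
        for ai, (name, zmag, (ox, oy)) in enumerate(_LIPID_LAYOUT):
            lipid_base[li, ai] = (sx + ox, sy + oy, sign * zmag)

    # ---- xanthophylls -----------------------------------------------------
    xan_names, body0, bidx = _xan_body(D)
    sign_beta = _torsion_sign(body0, bidx, primed=False)
    sign_eps = _torsion_sign(body0, bidx, primed=True)
    xan_atom_index: list[list[int]] = []
    for m in range(truth.n_xan):
        resid += 1
        rows = []
        resname = "XAN"
        for name in xan_names:
            rows.append(len(atoms))
            atoms.append(Atom(len(atoms), name, resname, resid))
        xan_atom_index.append(rows)
    xan_resids = [atoms[r[0]].residue_id for r in xan_atom_index]

    # ---- waters: bonding slots first, then bulk ---------------------------
    n_slot_waters = truth.n_xan * 2 * (truth.water_slots + 1)  # +1 bridge water
    if truth.n_water <= n_slot_waters:
        raise ValueError("n_water must exceed the number of bonding-slot waters")
    water_atom_index: list[list[int]] = []
    for w in range(truth.n_water):
        resid += 1
        rows = []
        for name in ("OW", "HW1", "HW2"):
            rows.append(len(atoms))
            atoms.append(Atom(len(atoms), name, "SOL", resid))
        water_atom_index.append(rows)

    n_atoms = len(atoms)
    coords = np.empty((n_frames, n_atoms, 3))

    # ---- lipid coordinates ------------------------------------------------
    flat = np.array([r for rows in lipid_atom_index for r in rows])
    jit = rng.normal(0.0, 1.0, size=(n_frames, len(flat), 3))
    jit[:, :, :2] *= truth.lipid_sigma_xy
    jit[:, :, 2] *= truth.lipid_sigma_z
    coords[:, flat, :] = lipid_base.reshape(1, -1, 3) + jit

    # ---- per-molecule schedules ------------------------------------------
    interface_mid = 0.5 * (truth.og_plane + truth.p_plane)
    eps_states_all, beta_states_all = [], []
    oh_world = {}  # (mol, ring) -> per-frame O position and direction

    for m, spec in enumerate(truth.xan):
        rows = np.array(xan_atom_index[m])
        beta_ang, beta_states = _markov_angles(rng, n_frames, spacing, truth.beta_torsion)
        eps_ang, eps_states = _markov_angles(rng, n_frames, spacing, truth.eps_torsion)
        beta_states_all.append(beta_states)
        eps_states_all.append(eps_states)

        # orientation schedule: tilt 0 (H) -> -90 (V, beta end down);
        # vertical-from-start molecules use +-90 by beta_end.
        tilt = np.zeros(n_frames)
        zc = np.zeros(n_frames)
        if spec.initial == "V":
            tilt[:] = 90.0 if spec.beta_end == "up" else -90.0
            zc[:] = 0.0
        else:
            tilt[:] = 0.0
            zc[:] = spec.leaflet * interface_mid
            if spec.flip_time is not None:
                t1 = spec.flip_time
                t0 = max(t1 - truth.transit_duration, 0.0)
                frac = np.clip((times - t0) / max(t1 - t0, spacing), 0.0, 1.0)
                # the epsilon end crosses the core: beta end stays in its
                # leaflet, so an upper-leaflet molecule ends beta-up
                final = 90.0 if spec.leaflet > 0 else -90.0
                tilt = frac * final
                zc = (1 - frac) * spec.leaflet * interface_mid
        # roll: plane label while horizontal, rotational diffusion once vertical
        up = spec.leaflet > 0
        beta_up = spec.plane_label == "beta_up"
        roll_h = 90.0 if (beta_up == up) else -90.0
        steps = rng.normal(0.0, math.sqrt(2 * truth.theta_diffusion * spacing),
                           size=n_frames)
        steps[0] = rng.uniform(0, 360)
        roll_v = np.cumsum(steps)
        vertical = np.abs(tilt) >= 89.999
        roll = np.where(vertical, roll_v, roll_h + rng.normal(0.0, 2.0, size=n_frames))

        com_jit = rng.normal(0.0, truth.xan_jitter, size=(n_frames, 3))
        cx, cy = spec.center_xy
        body = body0.copy()
        half = np.array([D / 2, 0.0, 0.0])
        for t in range(n_frames):
            body[bidx["K8"]] = place_dihedral(
                body[bidx["K5"]], body[bidx["K6"]], body[bidx["K7"]],
                1.5, 120.0, sign_beta * beta_ang[t],
            )
            body[bidx["K8P"]] = place_dihedral(
                body[bidx["K5P"]], body[bidx["K6P"]], body[bidx["K7P"]],
                1.5, 120.0, sign_eps * eps_ang[t],
            )
            R = _rotation(spec.azimuth, tilt[t], roll[t])
            center = np.array([cx, cy, zc[t]]) + com_jit[t]
            coords[t, rows] = center + (body - half) @ R.T
        for ring, o_name, h_name in (("beta", "OB", "HB"), ("eps", "OE", "HE")):
            o = coords[:, rows[bidx[o_name]]]
            h = coords[:, rows[bidx[h_name]]]
            d = h - o
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            oh_world[(m, ring)] = (o, d)

    # ---- bonding telegraphs and partner placement -------------------------
    n_oh = truth.n_xan * 2
    water_states = simulate_telegraph(
        rng, n_oh * truth.water_slots, n_frames, spacing, truth.water_telegraph
    )
    op_states = simulate_telegraph(rng, n_oh, n_frames, spacing, truth.op_telegraph)
    bridge_states = simulate_telegraph(
        rng, n_oh, n_frames, spacing, truth.bridge_telegraph
    )
    charge_states = simulate_telegraph(
        rng, n_oh, n_frames, spacing, truth.charge_telegraph
    )

    # anchor lipids: one per OH group, the first 2*n_xan lipids of the
    # matching leaflet list (these keep their natural P/glycerol positions;
    # only their Op oxygens and choline N are relocated while bonded)
    anchor_for_oh: dict[int, int] = {}
    upper_l = [i for i, s in enumerate(sites) if s[0] > 0]
    lower_l = [i for i, s in enumerate(sites) if s[0] < 0]
    iu = il = 0
    slot_water_iter = iter(range(n_slot_waters))
    bulk_start = n_slot_waters

    oh_list = [(m, ring) for m in range(truth.n_xan) for ring in ("beta", "eps")]
    for k, (m, ring) in enumerate(oh_list):
        spec = truth.xan[m]
        if spec.initial == "V":
            up = (ring == "beta") == (spec.beta_end == "up")
        else:
            up = spec.leaflet > 0
        if up:
            anchor_for_oh[k] = upper_l[iu % len(upper_l)]
            iu += 1
        else:
            anchor_for_oh[k] = lower_l[il % len(lower_l)]
            il += 1

    def orthobasis(d):
        # per-frame orthonormal complements of direction array d (n,3)
        ref = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(d, e1)
        return e1, e2

    for k, (m, ring) in enumerate(oh_list):
        o, d = oh_world[(m, ring)]
        e1, e2 = orthobasis(d)
        anchor = lipid_atom_index[anchor_for_oh[k]]
        a_names = [name for name, _, _ in _LIPID_LAYOUT]
        op1 = anchor[a_names.index("O13")]   # bridge partner
        op2 = anchor[a_names.index("O14")]   # direct H-bond partner
        n_at = anchor[a_names.index("N")]    # charge-pair partner

        # water slots: water-donor geometry at 60/120 deg off the OH axis
        for s in range(truth.water_slots):
            widx = water_atom_index[next(slot_water_iter)]
            ang = math.radians(60.0 + 60.0 * (s % 2))
            u = math.cos(ang) * d + math.sin(ang) * e1
            on = water_states[k * truth.water_slots + s]
            dist = np.where(on, 2.8, 6.0)[:, None]
            ow = o + dist * u
            to_o = (o - ow)
            to_o /= np.linalg.norm(to_o, axis=1, keepdims=True)
            coords[:, widx[0]] = ow
            coords[:, widx[1]] = ow + 0.96 * to_o           # HW1 donates to OH O
            coords[:, widx[2]] = ow + 0.96 * u              # HW2 points away
        # bridge water + relocated Op
        widx = water_atom_index[next(slot_water_iter)]
        on = bridge_states[k]
        ub = -e1
        dist = np.where(on, 2.8, 6.0)[:, None]
        ow = o + dist * ub
        to_o = (o - ow)
        to_o /= np.linalg.norm(to_o, axis=1, keepdims=True)
        coords[:, widx[0]] = ow
        coords[:, widx[1]] = ow + 0.96 * to_o
        coords[:, widx[2]] = ow + 0.96 * e2
        opb = ow + 2.8 * e2
        nat = coords[:, op1].copy()
        coords[:, op1] = np.where(on[:, None], opb, nat)
        # direct Op H-bond: collinear beyond the OH hydrogen (XAN donor)
        on = op_states[k]
        opd = o + 2.8 * d
        nat = coords[:, op2].copy()
        coords[:, op2] = np.where(on[:, None], opd, nat)
        # charge pair: choline N at 3.5 A, no angular requirement
        on = charge_states[k]
        npos = o + 3.5 * (math.cos(math.radians(110)) * d
                          + math.sin(math.radians(110)) * e2)
        nat = coords[:, n_at].copy()
        coords[:, n_at] = np.where(on[:, None], npos, nat)

    # ---- bulk waters ------------------------------------------------------
    n_bulk = truth.n_water - n_slot_waters
    zlow, zhigh = truth.p_plane + 4.0, box[2] / 2 - 2.0
    base_o = np.empty((n_bulk, 3))
    base_o[:, 0] = rng.uniform(0, box[0], n_bulk)
    base_o[:, 1] = rng.uniform(0, box[1], n_bulk)
    zmag = rng.uniform(zlow, zhigh, n_bulk)
    base_o[:, 2] = zmag * np.where(rng.random(n_bulk) < 0.5, 1.0, -1.0)
    bulk_rows = np.array([water_atom_index[bulk_start + i] for i in range(n_bulk)])
    jit = rng.normal(0.0, 0.3, size=(n_frames, n_bulk, 3))
    o_all = base_o[None, :, :] + jit
    coords[:, bulk_rows[:, 0]] = o_all
    coords[:, bulk_rows[:, 1]] = o_all + np.array([0.96, 0.0, 0.0])
    coords[:, bulk_rows[:, 2]] = o_all + np.array([-0.24, 0.93, 0.0])

    # shift everything so z in [0, box): slabs are built around z=0
    coords[:, :, 2] += box[2] / 2

    frames = [Frame(coords=coords[t], box=box.copy(), time=times[t])
              for t in range(n_frames)]
    traj = Trajectory(atoms, frames)
    traj._coords_cache = coords
    truth_out = truth
    truth_out.eps_state_series = np.array(eps_states_all)
    truth_out.beta_state_series = np.array(beta_states_all)
    truth_out.xan_resids = xan_resids
    return traj, truth_out


# --------------------------------------------------------------------------
# geometry-free fast paths
# --------------------------------------------------------------------------


def generate_event_matrix(
    populations,
    duration: float,
    spacing: float = 1.0,
    seed: int = 0,
    interaction: str = "hbond",
) -> BondEventMatrix:
    """Draw binary bond-event matrices straight from telegraph processes.

    ``populations`` is a sequence of dicts with keys ``n_pairs``, ``k_on``,
    ``k_off`` (and optionally ``partner_class``); coordinates are bypassed
    entirely, which makes large lifetime-statistics studies cheap.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / spacing)) + 1
    times = np.arange(n_frames) * spacing
    rows, pairs = [], []
    pid = 0
    for pop in populations:
        spec = TelegraphSpec(pop["k_on"], pop["k_off"])
        mat = simulate_telegraph(rng, int(pop["n_pairs"]), n_frames, spacing, spec)
        cls = pop.get("partner_class", "water")
        for r in range(mat.shape[0]):
            rows.append(mat[r])
            pairs.append(Bond(("SYN", pid, "beta"), cls, pid, pid))
            pid += 1
    return BondEventMatrix(interaction, pairs, np.array(rows), times)


def generate_decay_curve(
    fractions,
    taus,
    c0: float = 100.0,
    lag: float = 5000.0,
    spacing: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DecayCurve:
    """Analytic multi-exponential decay curve, optionally with Gaussian noise.

    ``fractions`` are percentage contributions (normalised to 100 by their
    own sum); ``taus`` are time constants in ps.
    """
    fractions = np.asarray(fractions, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if fractions.shape != taus.shape or fractions.ndim != 1:
        raise ValueError("fractions and taus must be 1-D and equally long")
    if np.any(fractions < 0) or np.any(taus <= 0):
        raise ValueError("fractions must be >= 0 and taus > 0")
    if fractions.sum() <= 0:
        raise ValueError("at least one fraction must be positive")
    w = fractions / fractions.sum()
    lags = np.arange(0.0, lag + spacing / 2, spacing)
    counts = c0 * np.sum(w[None, :] * np.exp(-lags[:, None] / taus[None, :]), axis=1)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        counts = counts + rng.normal(0.0, noise_sigma, size=counts.shape)
    return DecayCurve(lags, counts, n_origins=1, interaction="synthetic")
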