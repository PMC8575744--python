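"""Geometric detection and per-ps counting of the polar interactions that
anchor xanthophyll hydroxyls in the bilayer interface.

Three interaction types are detected per frame:

* **H-bonds** between a xanthophyll OH group and either a PC oxygen
  (non-esterified phosphate Op = O13/O14, carbonyl O22/O32) or a water
  molecule.  Criterion: donor-acceptor oxygen distance <= cutoff and
  donor-H...acceptor angle (at the hydrogen) >= a minimum.  The OH group
  is both donor and acceptor, so OH<->water is evaluated in both
  directions; PC oxygens can only accept.
* **Water bridges**: a water simultaneously H-bonded to the OH group and
  to a PC oxygen in the same frame.  Counted once per (OH, PC-oxygen)
  pair regardless of how many waters bridge it.
* **Charge pairs**: the OH oxygen within a distance cutoff of any choline
  N/CH3 atom of a lipid.

All distances use the minimum image convention; neighbour searches go
through a periodic KD-tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .classmap import AtomClassMap, ClassMapError
from .core import Frame, Trajectory, min_image_displacement

__all__ = [
    "HBondCriteria", "ChargePairCriteria", "Bond", "BondEventMatrix",
    "ContactTopology", "detect_hbonds", "detect_water_bridges",
    "detect_charge_pairs", "build_event_matrix", "summarize_contacts",
    "duration_panels",
]


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.25  # donor-acceptor oxygen distance, A
    min_dha_angle: float = 135.0   # D-H...A angle at the hydrogen, degrees

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class ChargePairCriteria:
    max_distance: float = 4.0  # OH oxygen to nearest choline N / CH3 carbon, A

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("distance cutoff must be positive")


class Bond(NamedTuple):
    """One detected interaction.

    oh            -- (resname, resid, ring) of the xanthophyll OH group
    partner_class -- 'Op' / 'O22' / 'O32' / 'water' / 'choline'
    partner_res   -- residue id of the partner molecule
    partner_atom  -- atom index of the partner atom (-1 for choline groups)
    """

    oh: tuple[str, int, str]
    partner_class: str
    partner_res: int
    partner_atom: int


@dataclass
class ContactTopology:
    """Index tables resolved once per topology for fast per-frame detection."""

    oh_groups: list[tuple[tuple[str, int, str], int, int]]  # (id, O idx, H idx)
    pc_ox: np.ndarray          # PC oxygen atom indices (Op + Oc)
    pc_ox_class: list[str]     # per index: 'Op' / 'O22' / 'O32'
    pc_ox_res: np.ndarray
    water_o: np.ndarray
    water_res: np.ndarray
    water_h: dict[int, np.ndarray]  # water resid -> H indices
    choline: dict[int, np.ndarray]  # lipid resid -> N + CH3 indices

    @classmethod
    def from_classmap(cls, cm: AtomClassMap) -> "ContactTopology":
        topo = cm.topology
        oh_groups = []
        for ring in ("beta", "eps"):
            o_by_res = cm.per_residue(f"xan_OH_O_{ring}")
            h_by_res = cm.per_residue(f"xan_OH_H_{ring}")
            for mol, o_idx in o_by_res.items():
                h_idx = h_by_res.get(mol)
                if h_idx is None or h_idx.size == 0:
                    raise ClassMapError(
                        f"OH oxygen of {mol} ({ring}) has no hydrogen in the topology"
                    )
                oh_groups.append(((mol[0], mol[1], ring), int(o_idx[0]), int(h_idx[0])))
        if not oh_groups:
            raise ClassMapError("no xanthophyll OH groups found")
        op = cm.select("Op")
        oc = cm.select("Oc")
        pc_ox = np.concatenate([op, oc]) if op.size or oc.size else np.array([], dtype=int)
        classes, res = [], []
        for i in pc_ox:
            a = topo[i]
            classes.append("Op" if i in set(op.tolist()) else a.name)
            res.append(a.residue_id)
        water_o = cm.select("water_O")
        water_res = np.array([topo[i].residue_id for i in water_o], dtype=int)
        water_h: dict[int, list[int]] = {}
        for i in cm.select("water_H"):
            water_h.setdefault(topo[i].residue_id, []).append(i)
        chol: dict[int, list[int]] = {}
        for i in np.concatenate([cm.select("choline_N"), cm.select("choline_CH3")]):
            chol.setdefault(topo[i].residue_id, []).append(int(i))
        return cls(
            oh_groups=oh_groups,
            pc_ox=pc_ox,
            pc_ox_class=classes,
            pc_ox_res=np.array(res, dtype=int),
            water_o=water_o,
            water_res=water_res,
            water_h={k: np.array(v, dtype=int) for k, v in water_h.items()},
            choline={k: np.array(v, dtype=int) for k, v in chol.items()},
        )


def _wrap(x, box):
    """Wrap coordinates into [0, box) robustly for periodic KD-trees."""
    w = np.mod(x, box)
    return np.where(w >= box, 0.0, w)


def _angle_at_h(h, d, a, box) -> float:
    """D-H...A angle in degrees (180 = linear)."""
    v1 = min_image_displacement(d, h, box)
    v2 = min_image_displacement(a, h, box)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _neighbors(tree: cKDTree, point: np.ndarray, box: np.ndarray, r: float):
    return tree.query_ball_point(_wrap(point, box), r)


def detect_hbonds(
    frame: Frame,
    classmap: AtomClassMap | ContactTopology,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[Bond]:
    """All OH<->PC-oxygen and OH<->water H-bonds of one frame."""
    ct = (
        classmap
        if isinstance(classmap, ContactTopology)
        else ContactTopology.from_classmap(classmap)
    )
    xyz, box = frame.coords, frame.box
    bonds: set[Bond] = set()
    cut = criteria.max_da_distance

    pc_tree = (
        cKDTree(_wrap(xyz[ct.pc_ox], box), boxsize=box) if ct.pc_ox.size else None
    )
    w_tree = (
        cKDTree(_wrap(xyz[ct.water_o], box), boxsize=box) if ct.water_o.size else None
    )

    for oh_id, o_idx, h_idx in ct.oh_groups:
        o = xyz[o_idx]
        # OH as donor to PC oxygens
        if pc_tree is not None:
            for k in _neighbors(pc_tree, o, box, cut):
                a_idx = ct.pc_ox[k]
                if _angle_at_h(xyz[h_idx], o, xyz[a_idx], box) >= criteria.min_dha_angle:
                    bonds.add(
                        Bond(oh_id, ct.pc_ox_class[k], int(ct.pc_ox_res[k]), int(a_idx))
                    )
        # OH <-> water, both directions
        if w_tree is not None:
            for k in _neighbors(w_tree, o, box, cut):
                wo_idx = int(ct.water_o[k])
                wres = int(ct.water_res[k])
                donor_ok = (
                    _angle_at_h(xyz[h_idx], o, xyz[wo_idx], box)
                    >= criteria.min_dha_angle
                )
                acceptor_ok = any(
                    _angle_at_h(xyz[wh], xyz[wo_idx], o, box) >= criteria.min_dha_angle
                    for wh in ct.water_h.get(wres, ())
                )
                if donor_ok or acceptor_ok:
                    bonds.add(Bond(oh_id, "water", wres, wo_idx))
    return bonds


def detect_water_bridges(
    frame: Frame,
    classmap: AtomClassMap | ContactTopology,
    criteria: HBondCriteria = HBondCriteria(),
    hbonds: set[Bond] | None = None,
) -> set[Bond]:
    """(OH, PC-oxygen) pairs bridged by a shared H-bonded water.

    A bridge exists when some water is H-bonded to the OH group (either
    direction) and simultaneously donates an H-bond to a PC oxygen.
    Counted at pair level: two bridging waters still give one bridge.
    """
    ct = (
        classmap
        if isinstance(classmap, ContactTopology)
        else ContactTopology.from_classmap(classmap)
    )
    if hbonds is None:
        hbonds = detect_hbonds(frame, ct, criteria)
    xyz, box = frame.coords, frame.box
    cut = criteria.max_da_distance
    pc_tree = (
        cKDTree(_wrap(xyz[ct.pc_ox], box), boxsize=box) if ct.pc_ox.size else None
    )
    if pc_tree is None:
        return set()
    bridges: set[Bond] = set()
    for b in hbonds:
        if b.partner_class != "water":
            continue
        wres, wo_idx = b.partner_res, b.partner_atom
        for k in _neighbors(pc_tree, xyz[wo_idx], box, cut):
            a_idx = int(ct.pc_ox[k])
            if any(
                _angle_at_h(xyz[wh], xyz[wo_idx], xyz[a_idx], box)
                >= criteria.min_dha_angle
                for wh in ct.water_h.get(wres, ())
            ):
                bridges.add(
                    Bond(b.oh, ct.pc_ox_class[k], int(ct.pc_ox_res[k]), a_idx)
                )
    return bridges


def detect_charge_pairs(
    frame: Frame,
    classmap: AtomClassMap | ContactTopology,
    criteria: ChargePairCriteria = ChargePairCriteria(),
) -> set[Bond]:
    """OH-oxygen / choline-group contacts within the distance cutoff."""
    ct = (
        classmap
        if isinstance(classmap, ContactTopology)
        else ContactTopology.from_classmap(classmap)
    )
    xyz, box = frame.coords, frame.box
    pairs: set[Bond] = set()
    if not ct.choline:
        return pairs
    chol_res = sorted(ct.choline)
    chol_idx = np.concatenate([ct.choline[r] for r in chol_res])
    chol_lab = np.concatenate(
        [np.full(len(ct.choline[r]), r) for r in chol_res]
    )
    tree = cKDTree(_wrap(xyz[chol_idx], box), boxsize=box)
    for oh_id, o_idx, _h in ct.oh_groups:
        for k in _neighbors(tree, xyz[o_idx], box, criteria.max_distance):
            pairs.add(Bond(oh_id, "choline", int(chol_lab[k]), -1))
    return pairs


@dataclass
class BondEventMatrix:
    """Boolean pair x frame record of firm bonding for one interaction type."""

    interaction: str
    pairs: list[Bond]
    matrix: np.ndarray  # bool, shape (n_pairs, n_frames)
    times: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.pairs), len(self.times)):
            raise ValueError("matrix dimensions inconsistent with pairs/times")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("pair identities must be unique")

    @property
    def counts_per_frame(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 1.0


_DETECTORS: dict[str, Callable] = {}


def _frame_detector(interaction: str, ct: ContactTopology, criteria):
    if interaction == "hbond":
        return lambda fr: detect_hbonds(fr, ct, criteria or HBondCriteria())
    if interaction == "water_bridge":
        return lambda fr: detect_water_bridges(fr, ct, criteria or HBondCriteria())
    if interaction == "charge_pair":
        return lambda fr: detect_charge_pairs(fr, ct, criteria or ChargePairCriteria())
    raise ValueError(f"unknown interaction {interaction!r}")


def build_event_matrix(
    traj: Trajectory,
    interaction: str = "hbond",
    classmap: AtomClassMap | None = None,
    criteria=None,
    stride: float | None = None,
    detector: Callable[[Frame], set[Bond]] | None = None,
) -> BondEventMatrix:
    """Evaluate a per-frame detector along the trajectory into a boolean
    pair x frame matrix.  ``stride`` (ps, default: the frame spacing) must
    be a multiple of the frame spacing."""
    dt = traj.dt
    step = (stride / dt) if stride is not None else 1.0
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError("stride must be a positive multiple of the frame spacing")
    step = int(round(step))
    if detector is None:
        if classmap is None:
            raise ValueError("classmap required when no detector is given")
        ct = ContactTopology.from_classmap(classmap)
        detector = _frame_detector(interaction, ct, criteria)
    frames = traj.frames[::step]
    times = traj.times[::step]
    per_frame = [detector(fr) for fr in frames]
    pairs = sorted({b for s in per_frame for b in s})
    row = {b: i for i, b in enumerate(pairs)}
    matrix = np.zeros((len(pairs), len(frames)), dtype=bool)
    for j, s in enumerate(per_frame):
        for b in s:
            matrix[row[b], j] = True
    return BondEventMatrix(interaction, list(pairs), matrix, np.asarray(times))


def summarize_contacts(
    matrix: BondEventMatrix,
    orientation_labels: dict[tuple[str, int], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Time-and-ensemble mean counts per OH group and partner class.

    Rows: partner classes plus an 'All' row summing the PC-oxygen classes
    (exact, before rounding).  Columns are grouped by ring and, when
    ``orientation_labels`` (per-molecule per-frame H/V/transit arrays,
    aligned with the matrix frames) are given, by orientation; transit
    frames are excluded from H/V summaries.
    """
    n_frames = matrix.matrix.shape[1]
    oh_ids = sorted({b.oh for b in matrix.pairs})
    classes = sorted({b.partner_class for b in matrix.pairs})
    pc_classes = [c for c in ("Op", "O22", "O32") if c in classes]

    def series(oh, cls) -> np.ndarray:
        rows = [i for i, b in enumerate(matrix.pairs) if b.oh == oh and b.partner_class == cls]
        return matrix.matrix[rows].sum(axis=0) if rows else np.zeros(n_frames)

    records = []
    for oh in oh_ids:
        mol = (oh[0], oh[1])
        if orientation_labels is not None and mol in orientation_labels:
            lab = np.asarray(orientation_labels[mol])
            groups = [("H", lab == "H"), ("V", lab == "V")]
        else:
            groups = [("all", np.ones(n_frames, dtype=bool))]
        per_class = {cls: series(oh, cls) for cls in classes}
        if pc_classes:
            per_class["All"] = sum(per_class[c] for c in pc_classes)
        for gname, mask in groups:
            if not mask.any():
                continue
            for cls, s in per_class.items():
                records.append(
                    {
                        "ring": oh[2],
                        "molecule": f"{oh[0]}:{oh[1]}",
                        "orientation": gname,
                        "partner": cls,
                        "mean_per_ps": float(s[mask].mean()),
                        "sd": float(s[mask].std(ddof=0)),
                        "n_frames": int(mask.sum()),
                    }
                )
    return pd.DataFrame.from_records(records)


def duration_panels(matrix: BondEventMatrix) -> dict:
    """Firm-bonding rasters per (OH group, partner molecule).

    Returns a mapping (oh, partner_class, partner_res) -> dict with the
    bonded time points and the maximal continuous episodes (start ps,
    end ps, n_frames).  This is the dot-raster view of individual
    interaction histories.
    """
    groups: dict[tuple, np.ndarray] = {}
    for i, b in enumerate(matrix.pairs):
        key = (b.oh, b.partner_class, b.partner_res)
        row = matrix.matrix[i]
        groups[key] = groups.get(key, np.zeros(row.shape, dtype=bool)) | row
    out = {}
    for key, bonded in groups.items():
        times = matrix.times[bonded]
        episodes = []
        i = 0
        n = len(bonded)
        while i < n:
            if bonded[i]:
                j = i
                while j + 1 < n and bonded[j + 1]:
                    j += 1
                episodes.append(
                    (float(matrix.times[i]), float(matrix.times[j]), j - i + 1)
                )
                i = j + 1
            else:
                i += 1
        out[key] = {"times": times, "episodes": episodes, "n_bonded": int(bonded.sum())}
    return out
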