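"""Minimum-image radial distribution functions between atom selections.

Normalisation uses the ideal-gas expectation from the instantaneous
orthorhombic box volume and the target number density, averaged over
frames.  In a bilayer slab this full-volume normalisation is comparative
(peak presence and relative height), not an absolute coordination measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Trajectory

__all__ = ["RDFResult", "compute_rdf"]


@dataclass
class RDFResult:
    bin_centers: np.ndarray  # A
    g: np.ndarray            # dimensionless
    r_max: float
    bin_width: float
    n_frames: int
    ref_label: str = "ref"
    target_label: str = "target"


def _wrap(x, box):
    w = np.mod(x, box)
    return np.where(w >= box, 0.0, w)


def compute_rdf(
    traj: Trajectory,
    sel_ref,
    sel_target,
    r_max: float = 10.0,
    bin_width: float = 0.1,
    ref_label: str = "ref",
    target_label: str = "target",
) -> RDFResult:
    """g(r) of ``sel_target`` atoms around ``sel_ref`` atoms.

    Selections may overlap (self-RDF): identical atom pairs are excluded
    and the target density uses N-1 where the selections are identical.
    ``r_max`` must not exceed half the smallest box length.
    """
    sel_ref = np.asarray(list(sel_ref), dtype=int)
    sel_target = np.asarray(list(sel_target), dtype=int)
    if sel_ref.size == 0 or sel_target.size == 0:
        raise ValueError("selections must be non-empty")
    self_rdf = set(sel_ref.tolist()) == set(sel_target.tolist())

    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    norm = 0.0
    for fr in traj.frames:
        box = fr.box
        if r_max > box.min() / 2:
            raise ValueError(
                f"r_max {r_max} A exceeds half the smallest box length {box.min() / 2} A"
            )
        ref_xyz = _wrap(fr.coords[sel_ref], box)
        tgt_xyz = _wrap(fr.coords[sel_target], box)
        tree = cKDTree(tgt_xyz, boxsize=box)
        shared = set(sel_ref.tolist()) & set(sel_target.tolist())
        for ri, atom_i in zip(ref_xyz, sel_ref):
            idx = tree.query_ball_point(ri, r_max)
            if idx:
                d = np.linalg.norm(
                    (tgt_xyz[idx] - ri) - box * np.round((tgt_xyz[idx] - ri) / box),
                    axis=1,
                )
                if int(atom_i) in shared:
                    d = d[np.asarray(sel_target)[idx] != atom_i]
                h, _ = np.histogram(d, bins=edges)
                counts += h
        volume = float(np.prod(box))
        n_tgt_eff = sel_target.size - 1 if self_rdf else sel_target.size
        density = n_tgt_eff / volume
        norm += sel_ref.size * density
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts / (shell * norm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        bin_centers=centers,
        g=g,
        r_max=r_max,
        bin_width=bin_width,
        n_frames=traj.n_frames,
        ref_label=ref_label,
        target_label=target_label,
    )
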