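"""Shared fixtures: a small synthetic bilayer and independent oracles."""

import numpy as np
import pytest

from xanmem.classmap import default_classmap
from xanmem.synthetic import default_truth, generate


@pytest.fixture(scope="session")
def small_system():
    """2 ns synthetic bilayer at 2 ps spacing, reduced water/lipid counts.

    Molecules: #0 V beta-up, #1 V beta-down, #2 H upper beta_up,
    #3 H lower beta_down, #4/#5 H with a flip completing at 900 ps.
    """
    truth = default_truth(duration=2000.0, seed=11, n_water=60, n_popc=60)
    traj, truth = generate(truth, 2000.0, spacing=2.0)
    return traj, truth


@pytest.fixture(scope="session")
def small_classmap(small_system):
    traj, _ = small_system
    return default_classmap(traj)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def brute_min_image(a, b, box):
    """Exhaustive search over the 27 periodic images."""
    best = np.inf
    a, b, box = map(np.asarray, (a, b, box))
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def brute_dihedral(p1, p2, p3, p4):
    """Textbook atan2(cross, dot) torsion formula, coded independently."""
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    return float(np.degrees(np.arctan2(y, x)))


def brute_crossing_count(labels):
    """Number of changes between assigned labels, unassigned transparent."""
    seq = [l for l in labels if l != "unassigned"]
    return sum(1 for a, b in zip(seq, seq[1:]) if a != b)


def brute_decay(matrix, origins, n_lag):
    """Naive double-loop returns-allowed decay recount."""
    acc = np.zeros(n_lag + 1)
    for i0 in origins:
        for pair in range(matrix.shape[0]):
            if matrix[pair, i0]:
                for tau in range(n_lag + 1):
                    if matrix[pair, i0 + tau]:
                        acc[tau] += 1
    return acc / len(origins)


def brute_hbonds(frame, ct, crit):
    """Independent H-bond double loop with explicit minimum-image search."""
    from xanmem.contacts import Bond
    xyz, box = frame.coords, frame.box

    def angle(h, d, a):
        v1 = np.array([xyz[d][i] - xyz[h][i] for i in range(3)])
        v2 = np.array([xyz[a][i] - xyz[h][i] for i in range(3)])
        v1 -= box * np.round(v1 / box)
        v2 -= box * np.round(v2 / box)
        c = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    found = set()
    for oh_id, o, h in ct.oh_groups:
        for k, a in enumerate(ct.pc_ox):
            if brute_min_image(xyz[o], xyz[a], box) <= crit.max_da_distance:
                if angle(h, o, a) >= crit.min_dha_angle:
                    found.add(Bond(oh_id, ct.pc_ox_class[k],
                                   int(ct.pc_ox_res[k]), int(a)))
        for k, wo in enumerate(ct.water_o):
            if brute_min_image(xyz[o], xyz[wo], box) <= crit.max_da_distance:
                wres = int(ct.water_res[k])
                ok = angle(h, o, wo) >= crit.min_dha_angle or any(
                    angle(wh, wo, o) >= crit.min_dha_angle
                    for wh in ct.water_h[wres]
                )
                if ok:
                    found.add(Bond(oh_id, "water", wres, int(wo)))
    return found


def brute_charge_pairs(frame, ct, crit):
    """Independent charge-pair double loop over choline groups."""
    from xanmem.contacts import Bond
    xyz, box = frame.coords, frame.box
    found = set()
    for oh_id, o, _ in ct.oh_groups:
        for res, idxs in ct.choline.items():
            if any(brute_min_image(xyz[o], xyz[i], box) <= crit.max_distance
                   for i in idxs):
                found.add(Bond(oh_id, "choline", int(res), -1))
    return found
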