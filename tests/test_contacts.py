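"""H-bond / water-bridge / charge-pair detection, event matrices and
contact summaries, with brute-force oracle equivalence."""

import numpy as np
import pytest

from xanmem.classmap import default_classmap
from xanmem.contacts import (
    Bond, BondEventMatrix, ChargePairCriteria, ContactTopology, HBondCriteria,
    build_event_matrix, detect_charge_pairs, detect_hbonds,
    detect_water_bridges, duration_panels, summarize_contacts,
)
from xanmem.core import Atom, Frame, Trajectory
from xanmem.synthetic import generate_event_matrix

from conftest import brute_charge_pairs, brute_hbonds, brute_min_image


def _frame(spec, box=40.0):
    """spec: list of (name, resname, resid, xyz)."""
    atoms = [Atom(i, n, rn, rid) for i, (n, rn, rid, _) in enumerate(spec)]
    xyz = np.array([p for *_, p in spec], dtype=float)
    return atoms, Frame(xyz, np.full(3, box), 0.0)


def _oh(resid=1, origin=(10.0, 10.0, 10.0), direction=(1.0, 0.0, 0.0)):
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    return [("OB", "XAN", resid, tuple(o)), ("HB", "XAN", resid, tuple(o + 0.96 * d))]


class TestHBondDetector:
    def test_collinear_acceptor_bonded(self):
        spec = _oh() + [("O13", "POPC", 2, (12.8, 10.0, 10.0))]
        atoms, frame = _frame(spec)
        bonds = detect_hbonds(frame, ContactTopology.from_classmap(
            default_classmap(Trajectory(atoms, [frame]))))
        assert len(bonds) == 1
        b = next(iter(bonds))
        assert b.partner_class == "Op" and b.oh[2] == "beta"

    def test_distance_cutoff(self):
        spec = _oh() + [("O13", "POPC", 2, (10.0, 14.0, 10.0))]
        atoms, frame = _frame(spec)
        cm = default_classmap(Trajectory(atoms, [frame]))
        assert detect_hbonds(frame, cm) == set()

    def test_angle_cutoff(self):
        # acceptor at 90 degrees from the O-H axis: d(O,A)=2.8 but bent
        spec = _oh() + [("O13", "POPC", 2, (10.0, 12.8, 10.0))]
        atoms, frame = _frame(spec)
        cm = default_classmap(Trajectory(atoms, [frame]))
        assert detect_hbonds(frame, cm) == set()

    def test_water_acceptor_direction(self):
        """Water donating to the xanthophyll O counts even when the
        xanthophyll H points elsewhere."""
        o = np.array([10.0, 10, 10])
        wo = o + np.array([0.0, 2.8, 0.0])
        h1 = wo + 0.96 * (o - wo) / np.linalg.norm(o - wo)
        spec = _oh() + [("OW", "SOL", 3, tuple(wo)), ("HW1", "SOL", 3, tuple(h1)),
                        ("HW2", "SOL", 3, tuple(wo + np.array([0.0, 0.96, 0.0])))]
        atoms, frame = _frame(spec)
        cm = default_classmap(Trajectory(atoms, [frame]))
        bonds = detect_hbonds(frame, cm)
        assert {b.partner_class for b in bonds} == {"water"}


class TestOracleEquivalence:
    @pytest.fixture(scope="class")
    @staticmethod
    def random_frames():
        """Dense random frames where cutoffs actually trigger."""
        rng = np.random.default_rng(42)
        spec_atoms = []
        # 4 OH groups
        for rid in range(1, 5):
            spec_atoms.append(("OB", "XAN", rid))
            spec_atoms.append(("HB", "XAN", rid))
        for rid in range(5, 25):  # PC oxygens + choline
            for name in ("O13", "O14", "O22", "O32", "N", "C13"):
                spec_atoms.append((name, "POPC", rid))
        for rid in range(25, 65):
            for name in ("OW", "HW1", "HW2"):
                spec_atoms.append((name, "SOL", rid))
        atoms = [Atom(i, n, rn, rid) for i, (n, rn, rid) in enumerate(spec_atoms)]
        frames = []
        box = 14.0  # small box: wraparound constantly exercised
        for t in range(60):
            xyz = rng.uniform(-box, 2 * box, (len(atoms), 3))
            # keep O-H geometry physical: H at 0.96 A from its O
            for i, a in enumerate(atoms):
                if a.name in ("HB", "HW1", "HW2"):
                    u = rng.normal(size=3)
                    xyz[i] = xyz[i - 1 if a.name != "HW2" else i - 2] + \
                        0.96 * u / np.linalg.norm(u)
            frames.append(Frame(np.mod(xyz, box), np.full(3, box), float(t)))
        traj = Trajectory(atoms, frames)
        return traj, ContactTopology.from_classmap(default_classmap(traj))

    def test_hbond_detector_matches_brute_force(self, random_frames):
        traj, ct = random_frames
        crit = HBondCriteria()
        n_bonds = 0
        for frame in traj.frames:
            ours = detect_hbonds(frame, ct, crit)
            brute = brute_hbonds(frame, ct, crit)
            assert ours == brute
            n_bonds += len(ours)
        assert n_bonds > 20  # the comparison actually exercised bonds

    def test_charge_detector_matches_brute_force(self, random_frames):
        traj, ct = random_frames
        crit = ChargePairCriteria()
        n = 0
        for frame in traj.frames:
            ours = detect_charge_pairs(frame, ct, crit)
            assert ours == brute_charge_pairs(frame, ct, crit)
            n += len(ours)
        assert n > 20

    def test_bridge_subset_property(self, random_frames):
        """Every bridge's OH group has a water H-bond in the same frame."""
        traj, ct = random_frames
        crit = HBondCriteria()
        total = 0
        for frame in traj.frames:
            hb = detect_hbonds(frame, ct, crit)
            wet = {b.oh for b in hb if b.partner_class == "water"}
            bridges = detect_water_bridges(frame, ct, crit, hbonds=hb)
            for b in bridges:
                assert b.oh in wet
                assert b.partner_class in ("Op", "O22", "O32")
            total += len(bridges)
        assert total > 0

    def test_translation_invariance(self, random_frames):
        """Counts are invariant under a rigid translation modulo the box."""
        traj, ct = random_frames
        crit = HBondCriteria()
        frame = traj.frames[0]
        shifted = Frame(frame.coords + np.array([5.3, -2.1, 9.9]), frame.box, 0.0)
        assert detect_hbonds(frame, ct, crit) == detect_hbonds(shifted, ct, crit)


class TestBridgeConventions:
    def _bridge_frame(self, n_waters=1):
        o = np.array([20.0, 20, 20])
        spec = _oh(origin=o)
        for w in range(n_waters):
            ang = np.radians(90.0 + 25.0 * w)
            u = np.array([np.cos(ang), np.sin(ang), 0.0])
            wo = o + 2.8 * u
            spec += [("OW", "SOL", 10 + w, tuple(wo)),
                     ("HW1", "SOL", 10 + w,
                      tuple(wo + 0.96 * (o - wo) / np.linalg.norm(o - wo))),
                     ("HW2", "SOL", 10 + w, tuple(wo + np.array([0, 0, 0.96])))]
        # one Op above both waters, reachable from each water's HW2
        spec += [("O13", "POPC", 2, (20.0 + 2.8 * np.cos(np.radians(102)),
                                     20.0 + 2.8 * np.sin(np.radians(102)), 22.8))]
        return _frame(spec)

    def test_single_bridge_detected(self):
        atoms, frame = self._bridge_frame(1)
        cm = default_classmap(Trajectory(atoms, [frame]))
        bridges = detect_water_bridges(frame, cm)
        assert len(bridges) == 1

    def test_two_waters_one_pair_level_bridge(self):
        """Two waters bridging the same (OH, Op) pair count once."""
        atoms, frame = self._bridge_frame(2)
        cm = default_classmap(Trajectory(atoms, [frame]))
        bridges = detect_water_bridges(frame, cm)
        assert len(bridges) == 1

    def test_water_bound_to_oh_only_is_no_bridge(self):
        o = np.array([20.0, 20, 20])
        wo = o + np.array([0, 2.8, 0.0])
        spec = _oh(origin=o) + [
            ("OW", "SOL", 10, tuple(wo)),
            ("HW1", "SOL", 10, tuple(wo + np.array([0, -0.96, 0.0]))),
            ("HW2", "SOL", 10, tuple(wo + np.array([0, 0.96, 0.0]))),
            ("O13", "POPC", 2, (35.0, 35.0, 35.0)),
        ]
        atoms, frame = _frame(spec)
        cm = default_classmap(Trajectory(atoms, [frame]))
        assert detect_water_bridges(frame, cm) == set()


class TestEventMatrix:
    def test_constant_detector_constant_rows(self, small_system, small_classmap):
        traj, _ = small_system
        sub = Trajectory(traj.topology, traj.frames[:20])
        fixed = detect_hbonds(sub.frames[0], small_classmap)
        m = build_event_matrix(sub, detector=lambda fr: fixed)
        assert m.matrix.all()
        assert m.matrix.shape == (len(fixed), 20)

    def test_column_sums_equal_per_frame_counts(self, small_system, small_classmap):
        traj, _ = small_system
        sub = Trajectory(traj.topology, traj.frames[:50])
        ct = ContactTopology.from_classmap(small_classmap)
        m = build_event_matrix(sub, "hbond", small_classmap)
        for j, frame in enumerate(sub.frames):
            assert m.counts_per_frame[j] == len(detect_hbonds(frame, ct))

    def test_telegraph_matrix_roundtrip(self):
        """A prescribed binary sequence survives matrix construction."""
        m = generate_event_matrix([{"n_pairs": 3, "k_on": 0.01, "k_off": 0.01}],
                                  duration=500.0, seed=9)
        assert m.matrix.shape == (3, 501)
        m2 = generate_event_matrix([{"n_pairs": 3, "k_on": 0.01, "k_off": 0.01}],
                                   duration=500.0, seed=9)
        assert np.array_equal(m.matrix, m2.matrix)  # seed determinism


class TestSummaries:
    def _matrix(self, rows, dt=1.0, oh=("XAN", 1, "beta"), cls="water"):
        rows = np.asarray(rows, dtype=bool)
        pairs = [Bond(oh, cls, 100 + i, 100 + i) for i in range(rows.shape[0])]
        return BondEventMatrix("hbond", pairs, rows,
                               np.arange(rows.shape[1]) * dt)

    def test_always_bonded(self):
        m = self._matrix(np.ones((1, 50)))
        s = summarize_contacts(m)
        row = s[s.partner == "water"].iloc[0]
        assert row.mean_per_ps == 1.0 and row.sd == 0.0

    def test_bernoulli_half(self):
        m = self._matrix((np.arange(100) % 2 == 0)[None, :])
        row = summarize_contacts(m).iloc[0]
        assert row.mean_per_ps == pytest.approx(0.5)
        assert row.sd == pytest.approx(0.5)

    def test_telegraph_stationary_mean(self):
        k_on, k_off = 0.003, 0.007  # p = 0.3
        m = generate_event_matrix(
            [{"n_pairs": 200, "k_on": k_on, "k_off": k_off}], duration=5000.0,
            seed=3)
        p_hat = m.matrix.mean()
        n_eff = 200 * 5000 * (k_on + k_off) / 2
        sd = np.sqrt(0.3 * 0.7 / n_eff)
        assert abs(p_hat - 0.3) < 3 * sd

    def test_all_row_is_exact_sum(self):
        rows = np.zeros((3, 40), dtype=bool)
        rows[0, ::2] = True   # Op
        rows[1, ::4] = True   # O22
        rows[2, ::5] = True   # O32
        oh = ("XAN", 1, "beta")
        pairs = [Bond(oh, "Op", 5, 50), Bond(oh, "O22", 6, 60), Bond(oh, "O32", 7, 70)]
        m = BondEventMatrix("hbond", pairs, rows, np.arange(40.0))
        s = summarize_contacts(m).set_index("partner")
        assert s.loc["All", "mean_per_ps"] == pytest.approx(
            s.loc[["Op", "O22", "O32"], "mean_per_ps"].sum())

    def test_orientation_grouping_excludes_transit(self):
        rows = np.ones((1, 30), dtype=bool)
        m = self._matrix(rows)
        labels = np.array(["H"] * 10 + ["transit"] * 10 + ["V"] * 10, dtype=object)
        s = summarize_contacts(m, orientation_labels={("XAN", 1): labels})
        assert set(s.orientation) == {"H", "V"}
        assert (s.n_frames == 10).all()


class TestDurationPanels:
    def test_episode_bookkeeping(self):
        rows = np.zeros((2, 100), dtype=bool)
        rows[0, 10:60] = True          # one 50-frame episode
        rows[1, ::2] = True            # alternating
        oh = ("XAN", 1, "beta")
        pairs = [Bond(oh, "O32", 5, 50), Bond(oh, "O32", 6, 60)]
        m = BondEventMatrix("hbond", pairs, rows, np.arange(100.0))
        panels = duration_panels(m)
        ep0 = panels[(oh, "O32", 5)]["episodes"]
        assert len(ep0) == 1 and ep0[0][2] == 50
        ep1 = panels[(oh, "O32", 6)]["episodes"]
        assert all(e[2] == 1 for e in ep1)
        # conservation: episode lengths sum to bonded frames
        for key, panel in panels.items():
            assert sum(e[2] for e in panel["episodes"]) == panel["n_bonded"]

    def test_partner_molecule_grouping_merges_atoms(self):
        """Two oxygen atoms of one lipid OR-combine into one raster."""
        rows = np.zeros((2, 10), dtype=bool)
        rows[0, :5] = True
        rows[1, 5:] = True
        oh = ("XAN", 1, "eps")
        pairs = [Bond(oh, "Op", 7, 70), Bond(oh, "Op", 7, 71)]
        m = BondEventMatrix("hbond", pairs, rows, np.arange(10.0))
        panels = duration_panels(m)
        assert len(panels) == 1
        assert panels[(oh, "Op", 7)]["n_bonded"] == 10


class TestGeneratorTruthRecovery:
    def test_stationary_means_within_3_sigma(self, small_system, small_classmap):
        """Per-partner-class contact means match the telegraph stationary
        probabilities of the generator truth."""
        traj, truth = small_system
        m = build_event_matrix(traj, "hbond", small_classmap)
        s = summarize_contacts(m)
        exp = truth.expected_means()
        n_oh = 2 * truth.n_xan
        for cls, key, relax in (("water", "water", truth.water_telegraph),
                                ("Op", "Op", truth.op_telegraph)):
            got = s[s.partner == cls].mean_per_ps.mean()
            p = exp[key]
            n_eff = n_oh * 2000.0 * relax.relaxation_rate / 2
            sd = np.sqrt(max(p, 0.05) / n_eff)  # Poisson-ish bound per class
            assert abs(got - p) < 3 * sd + 0.02

    def test_bridge_means(self, small_system, small_classmap):
        traj, truth = small_system
        m = build_event_matrix(traj, "water_bridge", small_classmap)
        rows = [i for i, b in enumerate(m.pairs) if b.partner_class == "Op"]
        got = m.matrix[rows].sum() / m.matrix.shape[1] / (2 * truth.n_xan)
        assert got == pytest.approx(truth.expected_means()["bridge"], abs=0.05)

    def test_charge_means(self, small_system, small_classmap):
        traj, truth = small_system
        m = build_event_matrix(traj, "charge_pair", small_classmap)
        got = m.matrix.sum() / m.matrix.shape[1] / (2 * truth.n_xan)
        assert got == pytest.approx(truth.expected_means()["choline"], abs=0.06)
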