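"""Interface references, H/V classification, reorientation events,
polyene-plane labels, long-axis rotation and structural scalars."""

import numpy as np
import pytest

from xanmem.classmap import ClassMapError, default_classmap
from xanmem.core import Atom, Frame, Trajectory
from xanmem.orientation import (
    InterfaceRef, check_aggregation, classify_orientation, hydrophobic_width,
    interface_reference, molecular_length, orientation_series,
    plane_orientation, theta_rotation,
)
from xanmem.synthetic import XanSpec, default_truth, generate


def _flat_ref(n, p=20.0, og=15.0, dt=1.0):
    t = np.arange(n) * dt
    ones = np.ones(n)
    return InterfaceRef(t, p * ones, -p * ones, og * ones, -og * ones, 0.0 * ones)


def _slab_traj(n_lipids=50, n_frames=20, sigma=0.0, shift=0.0, seed=0):
    """Minimal P/glycerol-O slab with optional jitter and z shift."""
    rng = np.random.default_rng(seed)
    atoms, rows = [], []
    for i in range(n_lipids):
        sign = 1 if i % 2 == 0 else -1
        for name, z in (("P", 20.0), ("O21", 15.0)):
            atoms.append(Atom(len(atoms), name, "POPC", i + 1))
            rows.append((sign, z))
    frames = []
    for t in range(n_frames):
        xyz = np.zeros((len(atoms), 3))
        xyz[:, 0] = rng.uniform(0, 80, len(atoms))
        xyz[:, 1] = rng.uniform(0, 80, len(atoms))
        xyz[:, 2] = [s * z + shift for s, z in rows]
        xyz[:, 2] += rng.normal(0, sigma, len(atoms)) + 40.0
        frames.append(Frame(xyz, np.array([80.0, 80.0, 80.0]), float(t)))
    return Trajectory(atoms, frames)


class TestInterfaceReference:
    def test_exact_construction(self):
        traj = _slab_traj()
        ref = interface_reference(traj, default_classmap(traj))
        assert np.allclose(ref.p_upper, 60.0)
        assert np.allclose(ref.p_lower, 20.0)
        assert np.allclose(ref.og_upper, 55.0)
        assert np.allclose(ref.og_lower, 25.0)
        assert np.allclose(ref.center, 40.0)

    def test_translation_covariance(self):
        a = interface_reference(_slab_traj(), default_classmap(_slab_traj()))
        t2 = _slab_traj(shift=3.0)
        b = interface_reference(t2, default_classmap(t2))
        for attr in ("p_upper", "p_lower", "og_upper", "og_lower", "center"):
            assert np.allclose(getattr(b, attr) - getattr(a, attr), 3.0)

    def test_noisy_slab_clt_bound(self):
        n_lip, sigma = 100, 1.0
        traj = _slab_traj(n_lipids=2 * n_lip, n_frames=200, sigma=sigma, seed=1)
        ref = interface_reference(traj, default_classmap(traj))
        se = sigma / np.sqrt(n_lip)
        assert abs(ref.p_upper.mean() - 60.0) < 3 * se / np.sqrt(200)

    def test_interface_ordering_enforced(self):
        n = 5
        with pytest.raises(ValueError):
            InterfaceRef(np.arange(n), np.full(n, 10.0), np.full(n, -10.0),
                         np.full(n, 12.0), np.full(n, -12.0), np.zeros(n))


class TestClassification:
    def test_vertical_all_frames_no_events(self):
        n = 200
        ref = _flat_ref(n)
        s = classify_orientation(np.full(n, 17.0), np.full(n, -17.0), ref,
                                 smoothing=10.0)
        assert np.all(s.labels == "V")
        assert s.events == []

    def test_constructed_ramp_yields_one_event(self):
        """100 ns H then a 20 ns ramp of one ring across the core -> one
        H->V event ending at ramp completion within the smoothing window."""
        dt, smooth = 100.0, 1000.0
        n = 2000  # 200 ns
        t = np.arange(n) * dt
        z_beta = np.full(n, 16.0)
        z_eps = np.full(n, 16.0)
        ramp = (t >= 100_000) & (t < 120_000)
        z_eps[ramp] = 16.0 - 33.0 * (t[ramp] - 100_000) / 20_000
        z_eps[t >= 120_000] = -17.0
        ref = _flat_ref(n, dt=dt)
        s = classify_orientation(z_beta, z_eps, ref, smoothing=smooth)
        assert len(s.events) == 1
        t0, t1, direction = s.events[0]
        assert direction == "H->V"
        # V becomes stable once z_eps enters the lower slab (z <= -13,
        # at 87.9% of the ramp), within the smoothing window
        t_enter = 100_000 + 20_000 * (16.0 + 13.0) / 33.0
        assert abs(t1 - t_enter) <= smooth + dt

    def test_generator_flip_detected_at_scheduled_time(self):
        """A truth-scheduled flip completing at 9 ns is timed within
        smoothing + frame stride."""
        duration, spacing, smooth = 20_000.0, 20.0, 500.0
        truth = default_truth(duration, seed=21, n_water=60, n_popc=60,
                              transit_duration=4000.0)
        traj, truth = generate(truth, duration, spacing)
        cm = default_classmap(traj)
        oss = orientation_series(traj, cm, smoothing=smooth)
        mols = cm.xan_residues()
        for i in (4, 5):
            events = oss[mols[i]].events
            assert len(events) == 1
            assert events[0][2] == "H->V"
            assert abs(events[0][1] - truth.xan[i].flip_time) <= smooth + spacing

    def test_z_mirror_invariance(self):
        n = 300
        rng = np.random.default_rng(7)
        zb = rng.uniform(13, 22, n)
        ze = rng.uniform(-22, -13, n)
        ref = _flat_ref(n)
        a = classify_orientation(zb, ze, ref, smoothing=5.0)
        b = classify_orientation(-zb, -ze, ref, smoothing=5.0)
        assert list(a.labels) == list(b.labels)  # V is mirror-symmetric

    def test_vertical_self_consistency(self, small_system, small_classmap):
        """>=99% of V-labelled frames have ring COMs on opposite sides of
        the bilayer centre."""
        traj, _ = small_system
        cm = small_classmap
        ref = interface_reference(traj, cm)
        for s in orientation_series(traj, cm, smoothing=100.0, ref=ref).values():
            mask = s.labels == "V"
            if mask.sum() == 0:
                continue
            opposite = (
                np.sign(s.z_beta[mask] - ref.center[mask])
                != np.sign(s.z_eps[mask] - ref.center[mask])
            )
            assert opposite.mean() >= 0.99


class TestPlaneOrientation:
    def test_generator_truth_recovered(self, small_system, small_classmap):
        traj, truth = small_system
        cm = small_classmap
        oss = orientation_series(traj, cm, smoothing=100.0)
        mols = cm.xan_residues()
        for i in (2, 3):  # stable horizontal molecules
            assert plane_orientation(traj, cm, oss[mols[i]]) == truth.xan[i].plane_label

    def test_mirror_logic_between_leaflets(self, small_system, small_classmap):
        """#2 (upper, beta_up) and #3 (lower, beta_down) have the same MET
        z-ordering convention after the leaflet mirror."""
        traj, truth = small_system
        assert truth.xan[2].leaflet == 1 and truth.xan[3].leaflet == -1

    def test_vertical_molecule_rejected(self, small_system, small_classmap):
        traj, _ = small_system
        cm = small_classmap
        oss = orientation_series(traj, cm, smoothing=100.0)
        with pytest.raises(ValueError):
            plane_orientation(traj, cm, oss[cm.xan_residues()[0]])


class TestThetaRotation:
    def _rotating_traj(self, deg_per_frame=10.0, n=37, horizontal=False):
        """One xanthophyll-like rod with a MET-C13 bond rotating about the
        long axis."""
        names = ["K3", "K3P", "K13", "MB2"]
        atoms = [Atom(i, n_, "XAN", 1) for i, n_ in enumerate(names)]
        frames = []
        for t in range(n):
            ang = np.radians(deg_per_frame * t)
            if horizontal:
                axis_a, axis_b = np.array([10.0, 40, 40]), np.array([38.3, 40, 40])
                mid = 0.5 * (axis_a + axis_b)
                bond = 1.5 * np.array([0.0, np.sin(ang), np.cos(ang)])
            else:
                axis_a, axis_b = np.array([40.0, 40, 12]), np.array([40, 40, 40.3])
                mid = 0.5 * (axis_a + axis_b)
                bond = 1.5 * np.array([np.cos(ang), np.sin(ang), 0.0])
            xyz = np.stack([axis_a, axis_b, mid + bond, mid])
            frames.append(Frame(xyz, np.array([80.0, 80, 80]), float(t) * 100.0))
        traj = Trajectory(atoms, frames)
        return traj

    def _series(self, traj, label):
        n = traj.n_frames
        from xanmem.orientation import OrientationSeries
        return OrientationSeries(("XAN", 1), traj.times, np.zeros(n), np.zeros(n),
                                 np.full(n, label, dtype=object),
                                 np.full(n, label, dtype=object))

    def test_full_turn_vertical(self):
        """10 degrees per 100 ps sample, 36 steps -> one full 360 turn."""
        traj = self._rotating_traj()
        cm = default_classmap(traj)
        rs = theta_rotation(traj, cm, self._series(traj, "V"), stride=100.0)
        sweep = rs.theta_unwrapped[-1] - rs.theta_unwrapped[0]
        assert abs(abs(sweep) - 360.0) < 1e-6
        assert np.all(np.abs(np.diff(rs.theta_unwrapped)) < 180.0)

    def test_frozen_bond_constant(self):
        traj = self._rotating_traj(deg_per_frame=0.0)
        cm = default_classmap(traj)
        rs = theta_rotation(traj, cm, self._series(traj, "V"), stride=100.0)
        assert np.nanstd(rs.theta) < 1e-9
        assert rs.theta_unwrapped[-1] == pytest.approx(rs.theta_unwrapped[0])

    def test_horizontal_convention_tracks_roll(self):
        traj = self._rotating_traj(deg_per_frame=5.0, horizontal=True)
        cm = default_classmap(traj)
        rs = theta_rotation(traj, cm, self._series(traj, "H"), stride=100.0)
        steps = np.diff(rs.theta_unwrapped)
        assert np.allclose(np.abs(steps), 5.0, atol=1e-6)

    def test_diffusive_rotation_msd(self):
        """Mean squared unwrapped angle grows as 2 D t (Brownian rotation)."""
        D = 0.06  # deg^2/ps
        truth = default_truth(4000.0, seed=31, n_water=60, n_popc=60,
                              theta_diffusion=D)
        traj, truth = generate(truth, 4000.0, spacing=4.0)
        cm = default_classmap(traj)
        oss = orientation_series(traj, cm, smoothing=100.0)
        mols = cm.xan_residues()
        disp = []
        for i in (0, 1):  # vertical molecules
            rs = theta_rotation(traj, cm, oss[mols[i]], stride=100.0)
            u = rs.theta_unwrapped
            lag = 10  # 1000 ps
            disp.extend((u[lag:] - u[:-lag]) ** 2)
        disp = np.asarray(disp)
        expect = 2 * D * 1000.0
        # chi^2-ish spread of the mean of correlated squared increments
        se = expect * np.sqrt(2.0 / (len(disp) / lag))
        assert abs(disp.mean() - expect) < 3 * se


class TestStructuralScalars:
    def test_molecular_length_exact_rod(self, small_system, small_classmap):
        """Rigid-rod C3-C3' distance is exactly the preset 28.3 A in every
        frame, invariant under the rigid motion of the molecules."""
        traj, truth = small_system
        df = molecular_length(traj, small_classmap)
        assert np.allclose(df["mean_A"], truth.rod_length, atol=1e-9)
        assert np.all(df["sd_A"] < 1e-9)

    def test_hydrophobic_width_recovers_construction(self, small_system,
                                                     small_classmap):
        traj, truth = small_system
        _, mean, sd = hydrophobic_width(traj, small_classmap)
        assert mean == pytest.approx(2 * truth.oc_plane, abs=0.05)

    def test_constructed_carbonyl_planes(self):
        """Carbonyl planes at +-15.15 A give a width of 30.3 A."""
        atoms, z = [], []
        for i in range(40):
            sign = 1 if i % 2 == 0 else -1
            for name, zz in (("P", 20.0), ("O22", 15.15)):
                atoms.append(Atom(len(atoms), name, "POPC", i + 1))
                z.append(sign * zz)
        xyz = np.zeros((len(atoms), 3))
        xyz[:, 2] = np.array(z) + 40.0
        traj = Trajectory(atoms, [Frame(xyz, np.array([80.0, 80, 80]), 0.0)])
        _, mean, _ = hydrophobic_width(traj, default_classmap(traj))
        assert mean == pytest.approx(30.3, abs=1e-9)


class TestAggregation:
    def _two_rods(self, gap, n_frames, overlap_frames=0):
        atoms = []
        for rid in (1, 2):
            for name in ("K3", "K13", "K3P"):
                atoms.append(Atom(len(atoms), name, "XAN", rid))
        frames = []
        for t in range(n_frames):
            d = 2.0 if t < overlap_frames else gap
            xyz = np.array(
                [[10.0, 10, 40], [24.0, 10, 40], [38.3, 10, 40],
                 [10.0, 10 + d, 40], [24.0, 10 + d, 40], [38.3, 10 + d, 40]]
            )
            frames.append(Frame(xyz, np.array([80.0, 80, 80]), float(t)))
        return Trajectory(atoms, frames)

    def test_separated_rods_no_episodes(self):
        traj = self._two_rods(gap=20.0, n_frames=50)
        assert check_aggregation(traj, default_classmap(traj)) == []

    def test_sustained_overlap_one_episode(self):
        traj = self._two_rods(gap=20.0, n_frames=50, overlap_frames=10)
        eps = check_aggregation(traj, default_classmap(traj), cutoff=4.0,
                                min_frames=5)
        assert len(eps) == 1
        assert eps[0]["n_frames"] == 10

    def test_transient_contacts_filtered(self):
        traj = self._two_rods(gap=20.0, n_frames=50, overlap_frames=1)
        assert check_aggregation(traj, default_classmap(traj), cutoff=4.0,
                                 min_frames=5) == []

    def test_default_system_does_not_aggregate(self, small_system, small_classmap):
        traj, _ = small_system
        sub = Trajectory(traj.topology, traj.frames[:100])
        assert check_aggregation(sub, small_classmap) == []
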