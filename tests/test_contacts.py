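"""H-bond / water-bridge detection and contact statistics."""

import itertools

import numpy as np
import pytest

from qosite.contacts import (
    ContactSeries,
    ContactSpec,
    Trajectory,
    contact_series,
    detect_bridge,
    detect_direct,
    hbond_lifetime,
    hydration_counts,
    moving_average,
)
from qosite.geometry import AtomSelection, Frame, ValidationError, distance
from qosite.synthetic import TelegraphSpec, telegraph_series


def _frame_with_waters(donor_xyz, acceptor_xyz, water_xyzs):
    ids = [("A", 1, "TYR", "OH"), ("A", 2, "GLU", "OE1")]
    coords = [donor_xyz, acceptor_xyz]
    for i, w in enumerate(water_xyzs):
        ids.append(("W", 100 + i, "HOH", "O"))
        coords.append(w)
    frame = Frame(ids, np.asarray(coords, dtype=float))
    donor = AtomSelection((ids[0],))
    acceptor = AtomSelection((ids[1],))
    waters = AtomSelection(tuple(ids[2:])) if water_xyzs else None
    return frame, donor, acceptor, waters


class TestDetectDirect:
    @pytest.mark.parametrize("d, formed", [(0.30, True), (0.35, False), (1.2, False)])
    def test_strict_cutoff(self, d, formed):
        frame, donor, acceptor, _ = _frame_with_waters((0, 0, 0), (d, 0, 0), [])
        spec = ContactSpec(donor=donor, acceptor=acceptor, bridge_order=0)
        assert detect_direct(frame, spec) is formed


class TestDetectBridge:
    def test_one_water_both_legs(self):
        frame, donor, acceptor, waters = _frame_with_waters(
            (0, 0, 0), (0.63, 0, 0), [(0.30, 0, 0)]
        )
        spec = ContactSpec(donor=donor, acceptor=acceptor, bridge_order=1)
        formed, chains = detect_bridge(frame, spec, waters)
        assert formed and chains == [(("W", 100, "HOH", "O"),)]

    def test_one_leg_fails(self):
        frame, donor, acceptor, waters = _frame_with_waters(
            (0, 0, 0), (0.66, 0, 0), [(0.30, 0, 0)]
        )  # water-acceptor leg is 0.36 nm
        spec = ContactSpec(donor=donor, acceptor=acceptor, bridge_order=1)
        formed, chains = detect_bridge(frame, spec, waters)
        assert not formed and chains == []

    def test_symmetric_under_donor_acceptor_swap(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            frame, donor, acceptor, waters = _frame_with_waters(
                rng.uniform(0, 1, 3), rng.uniform(0, 1, 3), list(rng.uniform(0, 1, (6, 3)))
            )
            fwd = detect_bridge(frame, ContactSpec(donor, acceptor, 1), waters)[0]
            rev = detect_bridge(frame, ContactSpec(acceptor, donor, 1), waters)[0]
            assert fwd == rev

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_exhaustive_chain_enumeration(self, k):
        """Random 12-water toy frames: bridge detection equals brute force over
        all ordered water tuples."""
        rng = np.random.default_rng(100 + k)
        cutoff = 0.35
        for _ in range(30):
            dxyz, axyz = rng.uniform(0, 1.2, 3), rng.uniform(0, 1.2, 3)
            wxyz = rng.uniform(0, 1.2, (12, 3))
            frame, donor, acceptor, waters = _frame_with_waters(dxyz, axyz, list(wxyz))
            spec = ContactSpec(donor=donor, acceptor=acceptor, bridge_order=k, cutoff=cutoff)
            formed, chains = detect_bridge(frame, spec, waters)
            expected = set()
            for perm in itertools.permutations(range(12), k):
                pts = [dxyz, *[wxyz[i] for i in perm], axyz]
                if all(distance(pts[i], pts[i + 1]) < cutoff for i in range(len(pts) - 1)):
                    expected.add(tuple(waters.atom_ids[i] for i in perm))
            assert set(chains) == expected
            assert formed == bool(expected)


class TestContactSeries:
    def test_all_formed_occupancy_one(self):
        cs = ContactSeries(formed=np.ones(50, dtype=bool), dt=0.002)
        assert cs.occupancy == 1.0

    def test_telegraph_occupancy_matches_stationary_law(self):
        spec = TelegraphSpec(k_on=2.0, k_off=2.0, dt=0.01, n_frames=100_000, seed=4)
        formed = telegraph_series(spec)
        cs = ContactSeries(formed=formed, dt=spec.dt)
        theta = 0.5
        rho = 1.0 - (spec.k_on + spec.k_off) * spec.dt
        se = np.sqrt(theta * (1 - theta) / spec.n_frames * (1 + rho) / (1 - rho))
        assert abs(cs.occupancy - theta) < 3 * se

    def test_square_wave_lifetimes(self):
        pulse = np.array(([True] * 10 + [False] * 10) * 20)
        cs = ContactSeries(formed=pulse, dt=0.002)
        lt = cs.lifetimes(gap_tolerance=0.0)
        assert np.allclose(lt, 0.020)

    def test_over_trajectory(self):
        frames = []
        for d in (0.30, 0.40, 0.32, 0.50):
            f, donor, acceptor, _ = _frame_with_waters((0, 0, 0), (d, 0, 0), [])
            frames.append(f)
        traj = Trajectory(frames=frames, dt=0.002)
        cs = contact_series(traj, ContactSpec(donor, acceptor, 0))
        assert list(cs.formed) == [True, False, True, False]
        assert cs.occupancy == 0.5

    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValidationError):
            Trajectory(frames=[None, None, None], dt=0.1, times=np.array([0.0, 0.1, 0.35]))


class TestMdTrajectoryLoader:
    PDB = (
        "MODEL        1\n"
        "ATOM      1  OH  TYR A 147      10.000  10.000  10.000  1.00  0.00           O\n"
        "ATOM      2  OE1 GLU A 295      13.000  10.000  10.000  1.00  0.00           O\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  OH  TYR A 147      10.000  10.000  10.000  1.00  0.00           O\n"
        "ATOM      2  OE1 GLU A 295      14.000  10.000  10.000  1.00  0.00           O\n"
        "ENDMDL\nEND\n"
    )

    def test_multi_model_pdb_as_trajectory(self, tmp_path):
        from qosite.contacts import load_md_trajectory

        path = tmp_path / "traj.pdb"
        path.write_text(self.PDB)
        traj = load_md_trajectory(str(path), dt=0.002)
        assert len(traj) == 2
        donor = AtomSelection((("A", 147, "TYR", "OH"),))
        acceptor = AtomSelection((("A", 295, "GLU", "OE1"),))
        cs = contact_series(traj, ContactSpec(donor, acceptor, 0))
        assert list(cs.formed) == [True, False]  # 0.30 nm formed, 0.40 nm not


class TestLifetime:
    def test_uninterrupted_run(self):
        cs = ContactSeries(formed=np.ones(100, dtype=bool), dt=0.004)
        assert hbond_lifetime(cs, gap_tolerance=0.0) == pytest.approx(100 * 0.004)

    def test_gap_merging_semantics(self):
        formed = np.array([True] * 5 + [False] + [True] * 5)
        cs = ContactSeries(formed=formed, dt=0.002)
        assert len(cs.lifetimes(gap_tolerance=0.0)) == 2
        merged = cs.lifetimes(gap_tolerance=cs.dt)
        assert len(merged) == 1
        assert merged[0] == pytest.approx(11 * 0.002)  # spans the tolerated gap

    def test_monotone_in_gap_tolerance(self):
        rng = np.random.default_rng(21)
        formed = rng.random(5000) < 0.4
        formed[0] = True
        cs = ContactSeries(formed=formed, dt=0.002)
        tolerances = [0.0, 0.002, 0.004, 0.01, 0.02]
        means = [hbond_lifetime(cs, t) for t in tolerances]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_telegraph_mean_lifetime_matches_off_rate(self):
        spec = TelegraphSpec(k_on=1.0, k_off=2.0, dt=0.01, n_frames=100_000, seed=8)
        cs = ContactSeries(formed=telegraph_series(spec), dt=spec.dt)
        lt = cs.lifetimes(gap_tolerance=0.0)
        expected = 1.0 / spec.k_off
        se = expected / np.sqrt(len(lt))
        assert abs(lt.mean() - expected) < 3 * se

    def test_never_formed_is_zero_with_warning(self):
        cs = ContactSeries(formed=np.zeros(10, dtype=bool), dt=0.002)
        with pytest.warns(UserWarning):
            assert hbond_lifetime(cs) == 0.0


class TestMovingAverage:
    def test_frame_weighted_mean_is_preserved(self):
        """With truncated edge windows, the window-size-weighted mean of the
        smoothed series equals the raw occupancy exactly."""
        import pandas as pd

        rng = np.random.default_rng(2)
        x = (rng.random(500) < 0.3).astype(float)
        dt, window = 0.002, 0.022  # 11-frame (odd, symmetric) window
        ma = moving_average(x, dt, window)
        w = int(round(window / dt))
        sizes = pd.Series(np.ones_like(x)).rolling(w, center=True, min_periods=1).sum().to_numpy()
        assert np.dot(ma, sizes) / sizes.sum() == pytest.approx(
            np.dot(x, sizes) / sizes.sum(), abs=1e-12
        )
        # and the unweighted means agree up to edge effects
        assert abs(ma.mean() - x.mean()) < w / len(x)

    def test_window_of_one_frame_is_identity(self):
        x = np.array([1.0, 0.0, 1.0, 1.0])
        assert np.array_equal(moving_average(x, 0.002, 0.002), x)


class TestHydration:
    def test_planted_counts_and_summary(self):
        frames = []
        for n_in in (2, 3, 4):
            waters = [(0.2, 0.01 * i, 0) for i in range(n_in)] + [(0.9, 0, 0)] * 2
            f, donor, _, _ = _frame_with_waters((0, 0, 0), (5, 5, 5), waters)
            frames.append((f, donor))
        center = frames[0][1]
        waters_sel = [AtomSelection(tuple(a for a in f.atom_ids if a[2] == "HOH")) for f, _ in frames]
        profiles = [
            hydration_counts([f], c, w, cutoff=0.35)
            for (f, c), w in zip(frames, waters_sel)
        ]
        counts = [p.counts[0] for p in profiles]
        assert counts == [2, 3, 4]

    def test_invariant_under_water_relabelling(self):
        rng = np.random.default_rng(6)
        wxyz = list(rng.uniform(0, 0.8, (8, 3)))
        f1, donor, _, w1 = _frame_with_waters((0, 0, 0), (5, 5, 5), wxyz)
        f2, _, _, w2 = _frame_with_waters((0, 0, 0), (5, 5, 5), wxyz[::-1])
        c1 = hydration_counts([f1], donor, w1, cutoff=0.35).counts
        c2 = hydration_counts([f2], donor, w2, cutoff=0.35).counts
        assert np.array_equal(c1, c2)

    def test_summary_ordering_invariant(self):
        from qosite.contacts import HydrationProfile

        p = HydrationProfile(label="x", counts=np.array([4, 2, 3]))
        assert p.min <= p.median <= p.max
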