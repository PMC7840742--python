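"""Tilt, insertion depth, solvation, hydrogen bonds, RDF, native contacts."""

import numpy as np
import pytest

import memperm as mp
from memperm.core_io import AtomSelection, TimeSeries, Topology, Trajectory
from memperm.interactions import (HBondCriteria, detect_hbonds,
                                  hbond_lifetimes, hydration_shell,
                                  insertion_depth, native_contacts, rdf,
                                  run_lengths, tilt_angle)
from memperm.selections import select


def _traj(coords, box=None, elements=None, names=None, resids=None,
          times=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    elements = np.array(elements if elements else ["O"] * n)
    top = Topology(
        names=np.array(names if names else [f"A{i}" for i in range(n)]),
        elements=elements,
        resnames=np.array(["MOL"] * n),
        resids=np.array(resids if resids is not None else np.arange(n)),
        charges=np.zeros(n),
        atomic_numbers=np.array([mp.core_io.atomic_number(e)
                                 for e in elements]),
    )
    if box is not None:
        box = np.tile(np.asarray(box, dtype=float), (coords.shape[0], 1))
    return top, Trajectory(coords=coords, box=box,
                           times=times if times is not None
                           else np.arange(coords.shape[0], dtype=float),
                           topology=top)


class TestTiltAngle:
    @pytest.mark.parametrize("vec,expected", [
        ([0, 0, 2.0], 0.0), ([1.5, 0, 0], 90.0), ([0, 0, -1.0], 180.0),
    ])
    def test_analytic_directions(self, vec, expected):
        coords = np.array([[[0, 0, 0], vec]])
        _, traj = _traj(coords)
        series, _, _ = tilt_angle(traj, head_atom=1, tail_atom=0)
        assert series.values[0] == pytest.approx(expected, abs=1e-9)

    def test_scripted_angles_peak_in_right_bins(self):
        angles = [32.0, 101.0, 149.0]  # off bin edges (5-degree bins)
        coords = np.zeros((3, 2, 3))
        for f, a in enumerate(angles):
            t = np.radians(a)
            coords[f, 1] = [np.sin(t), 0, np.cos(t)]
        _, traj = _traj(coords)
        series, hist, edges = tilt_angle(traj, 1, 0, bins=36)
        np.testing.assert_allclose(series.values, angles, atol=1e-9)
        occupied = np.nonzero(hist)[0]
        expected_bins = [int(a // 5) for a in angles]
        assert list(occupied) == expected_bins

    def test_coincident_atoms_error_names_frame(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1] = [0, 0, 1]
        _, traj = _traj(coords)
        with pytest.raises(ValueError, match="frame 1"):
            tilt_angle(traj, 1, 0)

    def test_isotropic_axis_symmetry(self, rng):
        """θ and 180°−θ are equidistributed for an isotropic axis."""
        n = 20_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        coords = np.zeros((n, 2, 3))
        coords[:, 1] = v
        _, traj = _traj(coords)
        series, _, _ = tilt_angle(traj, 1, 0)
        frac_up = np.mean(series.values < 90.0)
        assert frac_up == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))


class TestInsertionDepth:
    def _bilayer_with_permeant(self, perm_z, phos_z=(18.0, -18.0)):
        coords = [[5.0, 5.0, perm_z]]
        names, elements, resids = ["C1"], ["C"], [1]
        for i, z in enumerate(phos_z):
            coords.append([float(i), 0.0, z])
            names.append("P")
            elements.append("P")
            resids.append(2 + i)
        return _traj(np.array([coords]), box=[20.0, 20.0, 60.0],
                     elements=elements, names=names, resids=resids)

    def test_plane_convention(self):
        top, traj = self._bilayer_with_permeant(10.0)
        res = insertion_depth(traj, select(top, "name C1"),
                              select(top, "name P"))
        assert res.plane_mean == pytest.approx(8.0)

    def test_center_is_equidistant(self):
        top, traj = self._bilayer_with_permeant(0.0)
        res = insertion_depth(traj, select(top, "name C1"),
                              select(top, "name P"))
        assert res.plane_mean == pytest.approx(18.0)

    def test_scripted_path_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        path = 18.0 - np.abs(rng.normal(8, 4, 50))
        frames = []
        for z in path:
            frames.append([[5.0, 5.0, z], [0.0, 0.0, 18.0],
                           [1.0, 0.0, -18.0]])
        top, traj = _traj(np.array(frames), box=[20.0, 20.0, 60.0],
                          elements=["C", "P", "P"], names=["C1", "P", "P"],
                          resids=[1, 2, 3])
        res = insertion_depth(traj, select(top, "name C1"),
                              select(top, "name P"))
        brute = [min(abs(z - 18.0), abs(z + 18.0)) for z in path]
        assert res.plane_mean == pytest.approx(np.mean(brute), rel=1e-12)
        assert res.plane_sd == pytest.approx(np.std(brute), rel=1e-12)


class TestHydrationShell:
    def test_no_waters_gives_zero(self):
        top, traj = _traj(np.zeros((2, 1, 3)), box=[10, 10, 10])
        counts, _ = hydration_shell(traj, AtomSelection([0]),
                                    AtomSelection([]))
        assert np.all(counts == 0)

    def test_cutoff_is_inclusive_at_3p5(self):
        coords = [[0.0, 0, 0]]
        for r in (3.4, 3.4, 3.4, 3.4, 3.6, 3.6):
            coords.append([r, 0, 0])
            coords[-1][1] = len(coords) * 1e-9  # avoid exact duplicates
        top, traj = _traj(np.array([coords]), box=[50, 50, 50])
        counts, _ = hydration_shell(traj, AtomSelection([0]),
                                    AtomSelection(range(1, 7)), radius=3.5)
        assert counts[0, 0] == 4

    def test_matches_all_pairs_bruteforce(self, rng):
        n_frames, n_w = 25, 40
        coords = rng.uniform(0, 15, size=(n_frames, n_w + 2, 3))
        top, traj = _traj(coords, box=[15.0, 15.0, 30.0])
        centers = AtomSelection([0, 1])
        waters = AtomSelection(range(2, n_w + 2))
        counts, _ = hydration_shell(traj, centers, waters, radius=3.5)
        for f in range(n_frames):
            for ci, c in enumerate([0, 1]):
                brute = 0
                for w in range(2, n_w + 2):
                    d = coords[f, w] - coords[f, c]
                    d[0] -= 15.0 * round(d[0] / 15.0)
                    d[1] -= 15.0 * round(d[1] / 15.0)
                    if np.sqrt((d**2).sum()) <= 3.5:
                        brute += 1
                assert counts[f, ci] == brute

    def test_lateral_translation_invariance(self, rng):
        coords = rng.uniform(0, 12, size=(4, 20, 3))
        top, traj = _traj(coords, box=[12.0, 12.0, 24.0])
        c1, _ = hydration_shell(traj, AtomSelection([0]),
                                AtomSelection(range(1, 20)))
        moved = traj.coords + np.array([12.0 * 0.4, 12.0 * 1.7, 0.0])
        _, traj2 = _traj(moved, box=[12.0, 12.0, 24.0])
        c2, _ = hydration_shell(traj2, AtomSelection([0]),
                                AtomSelection(range(1, 20)))
        np.testing.assert_array_equal(c1, c2)


class TestHBonds:
    def _dha_traj(self, da_dist, collinear=True, n_frames=1):
        """Donor at origin, H 1 Å along x, acceptor on/off axis."""
        a_pos = [da_dist, 0, 0] if collinear else [0, da_dist, 0]
        coords = np.tile(np.array([[0.0, 0, 0], [1.0, 0, 0], a_pos]),
                         (n_frames, 1, 1))
        return _traj(coords, elements=["O", "H", "O"],
                     names=["OD", "HD", "OA"], resids=[1, 1, 2])

    def test_collinear_bond_detected(self):
        top, traj = self._dha_traj(2.8)
        ev = detect_hbonds(traj, AtomSelection([0]), AtomSelection([1]),
                           AtomSelection([2]))
        assert ev.presence[0, 0]

    def test_long_distance_rejected(self):
        top, traj = self._dha_traj(5.0)
        ev = detect_hbonds(traj, AtomSelection([0]), AtomSelection([1]),
                           AtomSelection([2]))
        assert not ev.presence[0, 0]

    def test_bent_geometry_rejected(self):
        """A 90° D–H⋯A angle fails the 135° default criterion."""
        top, traj = self._dha_traj(2.8, collinear=False)
        ev = detect_hbonds(traj, AtomSelection([0]), AtomSelection([1]),
                           AtomSelection([2]))
        assert not ev.presence[0, 0]

    def test_unbonded_hydrogen_rejected(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 0, 0], [5.0, 0, 0]]])
        top, traj = _traj(coords, elements=["O", "H", "O"])
        with pytest.raises(ValueError, match="not bonded"):
            detect_hbonds(traj, AtomSelection([0]), AtomSelection([1]),
                          AtomSelection([2]))

    def test_toggling_geometry_gives_toggle_pattern(self):
        pattern = np.array([1, 0, 1, 1, 0, 0, 1], dtype=bool)
        frames = []
        for on in pattern:
            d = 2.8 if on else 6.0
            frames.append([[0.0, 0, 0], [1.0, 0, 0], [d, 0, 0]])
        top, traj = _traj(np.array(frames), elements=["O", "H", "O"])
        ev = detect_hbonds(traj, AtomSelection([0]), AtomSelection([1]),
                           AtomSelection([2]))
        np.testing.assert_array_equal(ev.presence[0], pattern)


class TestLifetimes:
    def test_run_semantics_without_gap(self):
        assert run_lengths([1, 1, 1, 0, 1]) == [3, 1]

    def test_gap_tolerance_merges(self):
        assert run_lengths([1, 1, 1, 0, 1], gap_tolerance=1) == [5]

    def test_frame_conservation(self, rng):
        """Σ run lengths + Σ gap lengths = total frames (gap tolerance 0)."""
        p = rng.random(500) < 0.3
        runs = run_lengths(p)
        gaps = run_lengths(~p)
        assert sum(runs) + sum(gaps) == len(p)

    def test_table_shape_and_max(self):
        ev = mp.BondEventSeries(
            donors=np.array([0, 0]), hydrogens=np.array([1, 1]),
            acceptors=np.array([5, 6]),
            presence=np.array([[1, 1, 1, 0, 1], [0, 1, 0, 0, 0]], dtype=bool),
            frame_interval=1.0)
        table = hbond_lifetimes(ev)
        assert set(table.acceptor) == {5, 6}
        assert table.set_index("acceptor").loc[5, "max_lifetime"] == 3.0
        assert table.set_index("acceptor").loc[6, "max_lifetime"] == 1.0

    def test_telegraph_mean_lifetime_recovery(self):
        """Run-length lifetimes recover the telegraph generator's mean
        on-time within 3 standard errors."""
        from memperm.synthetic import telegraph_series
        series, truth = telegraph_series(5.0, 5.0, dt=0.02, n=1_000_000,
                                         seed=21)
        runs = np.array(run_lengths(series.values > 0.5)) * 0.02
        sem = runs.std() / np.sqrt(len(runs))
        assert runs.mean() == pytest.approx(truth["mean_on"], abs=3 * sem)
        # and the drawn dwells agree with the nominal mean at this n
        assert truth["mean_on"] == pytest.approx(5.0, abs=0.5)


class TestRDF:
    def test_ideal_gas_plateau(self, rng):
        """g(r) = 1 for two independent uniform selections.

        z is non-periodic by convention, so the box is tall in z to keep
        the slab-edge deficiency well below the tolerance."""
        n = 1000
        coords = rng.uniform(0, 30, size=(5, 2 * n, 3))
        coords[..., 2] *= 100.0 / 30.0
        top, traj = _traj(coords, box=[30.0, 30.0, 100.0])
        prof = rdf(traj, AtomSelection(range(n)),
                   AtomSelection(range(n, 2 * n)), r_max=8.0, dr=0.5,
                   density="box")
        plateau = prof.values[(prof.centers > 2.0)]
        assert np.mean(plateau) == pytest.approx(1.0, abs=0.05)

    def test_two_fixed_atoms_normalization(self):
        """A single pair at 3.5 Å occupies exactly one bin, with height
        equal to the hand-computed shell normalization."""
        coords = np.array([[[10.0, 10, 10], [13.5, 10, 10]]])
        top, traj = _traj(coords, box=[40.0, 40.0, 40.0])
        dr = 0.2
        prof = rdf(traj, AtomSelection([0]), AtomSelection([1]),
                   r_max=8.0, dr=dr, density="box")
        occupied = np.nonzero(prof.values)[0]
        k = int(3.5 / dr)
        assert list(occupied) == [k]
        r_mid = (k + 0.5) * dr
        rho = 1.0 / 40.0**3
        expected = 1.0 / (1 * rho * 4 * np.pi * r_mid**2 * dr)
        assert prof.values[k] == pytest.approx(expected, rel=1e-9)

    def test_counts_match_bruteforce(self, flat_bilayer, rng):
        top, traj, _ = flat_bilayer
        a = select(top, "name P")
        b = select(top, "resname WAT and element O")
        dr, r_max = 0.5, 10.0
        prof = rdf(traj, a, b, r_max=r_max, dr=dr)
        lx, ly = traj.box[0, 0], traj.box[0, 1]
        counts = np.zeros(len(prof.centers))
        for i in a.indices:
            for j in b.indices:
                d = traj.coords[0, j] - traj.coords[0, i]
                d[0] -= lx * round(d[0] / lx)
                d[1] -= ly * round(d[1] / ly)
                r = np.sqrt((d**2).sum())
                if r < r_max:
                    counts[int(r / dr)] += 1
        # same histogram => same profile after identical normalization
        zb = traj.coords[0, b.indices, 2]
        height = zb.max() - zb.min() + 2 * dr
        rho = len(b) / (lx * ly * height)
        shell = 4 * np.pi * prof.centers**2 * dr
        np.testing.assert_allclose(prof.values,
                                   counts / (len(a) * rho * shell), rtol=1e-9)

    def test_r_max_validated_against_box(self):
        top, traj = _traj(np.zeros((1, 2, 3)), box=[10.0, 10.0, 30.0])
        with pytest.raises(ValueError, match="half"):
            rdf(traj, AtomSelection([0]), AtomSelection([1]), r_max=6.0,
                dr=0.1)


class TestNativeContacts:
    def _pair_traj(self, separations):
        frames = [[[0.0, 0, 0], [0.0, 0, s], [3.0, 0, s]]
                  for s in separations]
        return _traj(np.array(frames), elements=["C", "C", "C"],
                     names=["D1", "L1", "L2"], resids=[1, 2, 2])

    def test_static_reference_gives_unity(self):
        top, traj = self._pair_traj([3.0, 3.0, 3.0])
        q = native_contacts(traj, AtomSelection([0]),
                            {"tail": AtomSelection([1, 2])}, cutoff=4.5,
                            reference_frame=0)
        np.testing.assert_allclose(q["tail"].values, 1.0)

    def test_departed_permeant_gives_zero(self):
        top, traj = self._pair_traj([3.0, 50.0, 50.0])
        q = native_contacts(traj, AtomSelection([0]),
                            {"tail": AtomSelection([1, 2])}, cutoff=4.5,
                            reference_frame=0)
        np.testing.assert_allclose(q["tail"].values[1:], 0.0)

    def test_partial_retention_gives_half(self):
        # reference: both lipid atoms within cutoff; later: one retained
        frames = np.array([
            [[0.0, 0, 0], [0, 0, 3.0], [3.0, 0, 0]],
            [[0.0, 0, 0], [0, 0, 3.0], [30.0, 0, 0]],
        ])
        top, traj = _traj(frames, elements=["C"] * 3)
        q = native_contacts(traj, AtomSelection([0]),
                            {"tail": AtomSelection([1, 2])}, cutoff=4.5,
                            reference_frame=0)
        assert q["tail"].values[1] == pytest.approx(0.5)

    def test_zero_reference_contacts_reports_absent(self):
        top, traj = self._pair_traj([50.0, 50.0])
        q = native_contacts(traj, AtomSelection([0]),
                            {"tail": AtomSelection([1, 2])}, cutoff=4.5,
                            reference_frame=0)
        assert q["tail"] is None
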