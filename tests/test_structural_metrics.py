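"""PDB parsing, RMSD metrics, superposition and trajectory profiles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import mtindex as m
from mtindex.errors import (
    PairingError,
    SelectionError,
    StructureParseError,
    SuperpositionError,
    TrajectoryError,
    WindowError,
)


def pdb_atom(serial, name, resname, chain, resseq, x, y, z, element=None):
    element = element or name[0]
    pname = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {pname}{resname:>4s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def translated_frame(frame, delta):
    dx, dy, dz = delta
    return m.Frame([
        m.AtomRecord(a.serial, a.name, a.resname, a.chain, a.resseq, a.element,
                     (a.xyz[0] + dx, a.xyz[1] + dy, a.xyz[2] + dz))
        for a in frame.atoms
    ])


def numeric_min_rmsd(mobile, reference):
    """Brute-force minimization over proper rotations (rotation-vector
    parameterization, multi-start Nelder-Mead); independent of the SVD path."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def loss(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ rot.T - ref_c) ** 2, axis=1)))

    starts = [np.zeros(3), [np.pi, 0, 0], [0, np.pi, 0], [0, 0, np.pi],
              [np.pi / 2] * 3, [-np.pi / 2, np.pi / 2, 0.0]]
    return min(
        minimize(loss, s, method="Nelder-Mead",
                 options=dict(xatol=1e-12, fatol=1e-14, maxiter=4000)).fun
        for s in starts
    )


class TestParseStructure:
    def test_multi_model_ligand(self, tmp_path):
        lines = []
        for model in range(1, 4):
            lines.append(f"MODEL     {model:4d}")
            for i in range(5):
                lines.append(pdb_atom(i + 1, f"C{i+1}", "LIG", "L", 1,
                                      float(i), float(model), 0.0, "C"))
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "lig.pdb"
        path.write_text("\n".join(lines) + "\n")
        traj = m.parse_structure(path)
        assert len(traj) == 3
        assert all(len(f) == 5 for f in traj.frames)

    def test_single_model_backbone_selection(self, tmp_path):
        lines = []
        serial = 0
        for resseq in (1, 2):
            for name in ("N", "CA", "C", "O", "CB"):
                serial += 1
                lines.append(pdb_atom(serial, name, "ALA", "A", resseq,
                                      float(serial), 0.0, 0.0))
        path = tmp_path / "prot.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        traj = m.parse_structure(path)
        assert len(traj) == 1
        sel = m.AtomSelection(names=frozenset(["N", "CA", "C"]))
        assert len(sel.indices(traj.frames[0])) == 6  # 3 per residue

    def test_altloc_other_than_blank_or_a_skipped(self, tmp_path):
        base = pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
        alt_a = base[:16] + "A" + base[17:]
        alt_b = pdb_atom(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0)
        alt_b = alt_b[:16] + "B" + alt_b[17:]
        path = tmp_path / "alt.pdb"
        path.write_text(alt_a + "\n" + alt_b + "\nEND\n")
        traj = m.parse_structure(path)
        assert len(traj.frames[0]) == 1
        assert traj.frames[0].atoms[0].xyz == (0.0, 0.0, 0.0)

    def test_generator_round_trip_within_format_precision(self, tmp_path):
        cfg = m.SyntheticTrajectoryConfig(n_frames=4, noise_sigma=0.2, seed=8)
        traj = m.simulate_trajectory(cfg)
        path = tmp_path / "traj.pdb"
        m.write_trajectory_pdb(traj, path)
        back = m.parse_structure(path)
        assert len(back) == len(traj)
        for a, b in zip(traj.frames, back.frames):
            assert a.identity_sequence() == b.identity_sequence()
            assert np.abs(a.coords - b.coords).max() <= 1e-3

    def test_malformed_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1      xx.xxx   1.000   1.000"
            "  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(StructureParseError, match="line"):
            m.parse_structure(path)

    def test_inconsistent_model_atom_counts_rejected(self, tmp_path):
        lines = ["MODEL        1",
                 pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
                 pdb_atom(2, "CB", "ALA", "A", 1, 1, 0, 0),
                 "ENDMDL",
                 "MODEL        2",
                 pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
                 "ENDMDL", "END"]
        path = tmp_path / "mismatch.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryError):
            m.parse_structure(path)


class TestSelectionParsing:
    def test_compact_string_with_multi_names(self):
        sel = m.AtomSelection.parse("chain:A,resseq:238,resname:SER,names:OG,CB")
        assert sel.chain == "A"
        assert sel.resseq == 238
        assert sel.resname == "SER"
        assert sel.names == frozenset(["OG", "CB"])

    def test_dangling_token_rejected(self):
        with pytest.raises(SelectionError):
            m.AtomSelection.parse("resseq:1,CB")


class TestInplaceRmsd:
    @pytest.fixture()
    def frame(self, rng):
        return m.Frame([
            m.AtomRecord(i + 1, "CA", "ALA", "A", i + 1, "C", tuple(map(float, xyz)))
            for i, xyz in enumerate(rng.normal(size=(20, 3)))
        ])

    def test_identical_frames_give_zero(self, frame):
        assert m.inplace_rmsd(frame, frame) == 0.0

    def test_uniform_translation_gives_its_norm(self, frame):
        assert m.inplace_rmsd(frame, translated_frame(frame, (3, 4, 0))) == pytest.approx(5.0)

    def test_matches_per_atom_brute_force(self, frame, rng):
        other = m.Frame([
            m.AtomRecord(a.serial, a.name, a.resname, a.chain, a.resseq, a.element,
                         tuple(float(v) for v in rng.normal(size=3)))
            for a in frame.atoms
        ])
        total = sum(
            sum((p - q) ** 2 for p, q in zip(a.xyz, b.xyz))
            for a, b in zip(frame.atoms, other.atoms)
        )
        oracle = (total / len(frame)) ** 0.5
        assert m.inplace_rmsd(frame, other) == pytest.approx(oracle, abs=1e-12)
        assert m.inplace_rmsd(other, frame) == m.inplace_rmsd(frame, other)

    def test_count_mismatch_raises(self, frame):
        short = m.Frame(frame.atoms[:5])
        with pytest.raises(PairingError):
            m.inplace_rmsd(frame, short)


class TestKabsch:
    def test_rigid_copy_recovered_exactly(self, rng):
        ref = rng.normal(size=(12, 3))
        rot = Rotation.from_rotvec([0, 0, np.pi / 2])
        mobile = rot.apply(ref) + np.array([1.0, -2.0, 0.5])
        result = m.kabsch_superpose(mobile, ref)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        # recovered rotation inverts the applied one
        assert np.allclose(result.rotation, rot.inv().as_matrix(), atol=1e-9)
        assert np.allclose(result.apply(mobile), ref, atol=1e-9)

    def test_mirror_image_of_chiral_set_cannot_align(self):
        points = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mirror = points * np.array([1, 1, -1])
        result = m.kabsch_superpose(mirror, points)
        assert result.rmsd > 0.1  # reflections are excluded
        assert result.rmsd == pytest.approx(numeric_min_rmsd(mirror, points), abs=1e-6)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_numeric_optimizer_on_noisy_instances(self):
        """SVD solution == brute-force minimum over proper rotations (30 runs)."""
        rng = np.random.default_rng(2024)
        for _ in range(30):
            ref = rng.normal(size=(20, 3))
            mobile = (Rotation.random(rng=rng).apply(ref)
                      + rng.normal(size=3)
                      + rng.normal(0.0, 0.3, size=(20, 3)))
            analytic = m.kabsch_superpose(mobile, ref).rmsd
            assert analytic == pytest.approx(numeric_min_rmsd(mobile, ref), abs=1e-6)

    def test_superposition_never_exceeds_inplace(self, rng):
        coords_a = rng.normal(size=(15, 3))
        coords_b = coords_a + rng.normal(0.0, 1.0, size=(15, 3))
        frame_a = m.Frame([
            m.AtomRecord(i, "CA", "ALA", "A", i + 1, "C", tuple(map(float, p)))
            for i, p in enumerate(coords_a)
        ])
        frame_b = m.Frame([
            m.AtomRecord(i, "CA", "ALA", "A", i + 1, "C", tuple(map(float, p)))
            for i, p in enumerate(coords_b)
        ])
        assert m.kabsch_superpose(coords_a, coords_b).rmsd <= m.inplace_rmsd(
            frame_a, frame_b
        ) + 1e-12

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(SuperpositionError):
            m.kabsch_superpose(line, line)


class TestBackboneRmsdProfile:
    def test_rigid_motion_nulled_by_superposition(self):
        traj = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(n_frames=10, noise_sigma=0.0, seed=2)
        )
        profile = m.backbone_rmsd_profile(traj)
        assert profile.values.max() < 1e-5

    def test_constant_trajectory_is_flat_zero(self):
        traj = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(
                n_frames=5, rotation_deg_per_frame=0.0,
                translation_per_frame=0.0, seed=2,
            )
        )
        profile = m.backbone_rmsd_profile(traj)
        assert len(profile) == 5
        assert np.allclose(profile.values, 0.0, atol=1e-12)
        assert np.allclose(profile.times, np.arange(5) * traj.dt)

    def test_gaussian_jitter_matches_analytic_expectation(self):
        """Isotropic jitter sigma per coordinate gives E[RMSD] ~ sqrt(3) sigma
        against a noise-free reference (10% Monte-Carlo band, fixed seed)."""
        sigma = 0.5
        noisy = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(n_frames=100, noise_sigma=sigma, seed=9)
        )
        clean = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(n_frames=100, noise_sigma=0.0, seed=9)
        )
        profile = m.backbone_rmsd_profile(noisy, reference=clean.frames[0])
        expected = np.sqrt(3.0) * sigma
        assert abs(profile.values.mean() - expected) < 0.1 * expected

    def test_invariant_under_global_rigid_transform(self):
        traj = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(n_frames=6, noise_sigma=0.3, seed=4)
        )
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        shift = np.array([5.0, -3.0, 2.0])
        moved_frames = []
        for frame in traj.frames:
            coords = rot.apply(frame.coords) + shift
            moved_frames.append(m.Frame([
                m.AtomRecord(a.serial, a.name, a.resname, a.chain, a.resseq,
                             a.element, tuple(map(float, xyz)))
                for a, xyz in zip(frame.atoms, coords)
            ]))
        moved = m.Trajectory(frames=moved_frames, dt=traj.dt)
        base_profile = m.backbone_rmsd_profile(traj, reference=traj.frames[0])
        moved_profile = m.backbone_rmsd_profile(moved, reference=moved.frames[0])
        assert np.allclose(base_profile.values, moved_profile.values, atol=1e-6)


class TestDistanceProfile:
    def test_planted_linear_ramp_reproduced(self, ligand_c1, serine_og):
        traj = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(
                n_frames=31, noise_sigma=0.0, seed=3,
                approach=m.PlantedApproach(start=5.0, end=2.0),
            )
        )
        profile = m.distance_profile(traj, ligand_c1, serine_og, mode="pair")
        expected = np.linspace(5.0, 2.0, 31)
        assert np.allclose(profile.values, expected, atol=1e-3)

    def test_same_atom_pair_distance_is_zero(self, serine_og):
        traj = m.simulate_trajectory(m.SyntheticTrajectoryConfig(n_frames=3, seed=1))
        profile = m.distance_profile(traj, serine_og, serine_og, mode="pair")
        assert np.allclose(profile.values, 0.0)

    def test_min_mode_matches_pairwise_brute_force(self):
        traj = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(n_frames=4, noise_sigma=0.4, seed=6)
        )
        lig = m.AtomSelection(resname="LIG")
        res = m.AtomSelection(resname="SER")
        profile = m.distance_profile(traj, lig, res, mode="min")
        for k, frame in enumerate(traj.frames):
            lig_atoms = [a for a in frame.atoms if a.resname == "LIG"]
            res_atoms = [a for a in frame.atoms if a.resname == "SER"]
            oracle = min(
                sum((p - q) ** 2 for p, q in zip(a.xyz, b.xyz)) ** 0.5
                for a in lig_atoms for b in res_atoms
            )
            assert profile.values[k] == pytest.approx(oracle, abs=1e-12)

    def test_min_mode_invariant_to_atom_order(self):
        traj = m.simulate_trajectory(
            m.SyntheticTrajectoryConfig(n_frames=3, noise_sigma=0.2, seed=5)
        )
        reversed_frames = [
            m.Frame(tuple(reversed(frame.atoms))) for frame in traj.frames
        ]
        reversed_traj = m.Trajectory(frames=reversed_frames, dt=traj.dt)
        lig, res = m.AtomSelection(resname="LIG"), m.AtomSelection(resname="SER")
        forward = m.distance_profile(traj, lig, res, mode="min")
        backward = m.distance_profile(reversed_traj, lig, res, mode="min")
        assert np.allclose(forward.values, backward.values)

    def test_empty_selection_names_the_filter(self):
        traj = m.simulate_trajectory(m.SyntheticTrajectoryConfig(n_frames=3, seed=1))
        with pytest.raises(SelectionError, match="ligand"):
            m.distance_profile(
                traj, m.AtomSelection(resname="XXX"), m.AtomSelection(resname="SER")
            )


class TestSummarizeProfile:
    def test_constant_series(self):
        ts = m.TimeSeries(times=np.arange(5.0), values=np.full(5, 3.3))
        s = m.summarize_profile(ts)
        assert s.mean == s.min == s.max == 3.3

    def test_burn_in_keeps_suffix_only(self):
        values = np.arange(1.0, 11.0)
        ts = m.TimeSeries(times=np.arange(10.0), values=values)
        s = m.summarize_profile(ts, burn_in=5.0)
        assert s.n_frames == 5
        assert s.mean == pytest.approx(sum(range(6, 11)) / 5.0)
        assert (s.first, s.last) == (6.0, 10.0)

    def test_zero_burn_in_covers_full_series(self):
        ts = m.TimeSeries(times=np.arange(4.0), values=np.array([1.0, 2, 3, 4]))
        assert m.summarize_profile(ts, 0.0).n_frames == 4

    def test_empty_window_raises(self):
        ts = m.TimeSeries(times=np.arange(3.0), values=np.zeros(3))
        with pytest.raises(WindowError):
            m.summarize_profile(ts, burn_in=10.0)
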