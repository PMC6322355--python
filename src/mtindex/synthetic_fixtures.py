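"""Deterministic synthetic data: score tables and trajectories.

Two seeded generators make every analysis module testable without any
external docking engine or MD run:

* :func:`simulate_score_table` emulates a docking-based virtual screen —
  per-target, roughly normal, strictly negative score distributions over
  a compound library, with an optional handful of planted multitarget
  binders placed just above each target's minimum so they dominate the
  multitarget indices without tying.
* :func:`simulate_trajectory` emulates an MD snapshot series — a rigid
  body motion of a random protein-like backbone plus isotropic Gaussian
  coordinate jitter, with an optional planted ligand-approach trend whose
  pair distance ramps linearly (e.g. 4.8 to 3.0 Angstrom) before noise.

Both generators draw from one ``numpy`` Generator seeded per invocation,
so identical configurations yield byte-identical outputs. The module also
exposes the packaged fixture transcribing the published docking-score
tables for the Calceolaria compound library (targets EcR, PPO, DmAChE,
hAChE), used throughout the tests and the worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .score_model import ScoreRecord, ScoreTable, read_score_table
from .structural_metrics import AtomRecord, Frame, Trajectory

_ELEMENT_BY_NAME = {"N": "N", "CA": "C", "C": "C", "OG": "O"}


def published_scores_path() -> Path:
    """Path of the packaged fixture of published per-structure scores."""
    return Path(resources.files("mtindex") / "fixtures" / "paper_tables.csv")


def load_published_scores() -> ScoreTable:
    """The published per-structure docking scores of the top-ranked
    Calceolaria metabolites against EcR, PPO, DmAChE and hAChE."""
    return read_score_table(published_scores_path())


# ---------------------------------------------------------------------------
# score tables


@dataclass(frozen=True)
class SyntheticScoreConfig:
    """Conditions of a simulated virtual screen.

    Defaults emulate a screen of ~100 natural products against four
    targets with two receptor structures each: per-target scores centered
    at -120 with spread 25 (the published top-10 window spans roughly
    -137 to -215), small per-structure scatter, and three planted
    multitarget binders.
    """

    n_compounds: int = 100
    targets: tuple[str, ...] = ("EcR", "PPO", "DmAChE", "hAChE")
    structures_per_target: int = 2
    score_mean: float = -120.0
    score_sd: float = 25.0
    structure_sd: float = 2.0
    n_multitarget: int = 3
    margin_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if not self.targets:
            raise ConfigError("at least one target required")
        if self.structures_per_target < 1:
            raise ConfigError("structures_per_target must be >= 1")
        if self.score_mean >= 0:
            raise ConfigError("score_mean must be negative (docking convention)")
        if self.score_sd < 0 or self.structure_sd < 0:
            raise ConfigError("spreads must be non-negative")
        if not 0 <= self.n_multitarget <= self.n_compounds:
            raise ConfigError("n_multitarget must lie in [0, n_compounds]")
        if self.margin_frac <= 0:
            raise ConfigError("margin_frac must be positive")


def simulate_score_table(cfg: SyntheticScoreConfig) -> ScoreTable:
    """Generate a complete (compound x target x structure) score table.

    The first ``n_multitarget`` compounds are planted at each target's
    background minimum plus ``margin_frac`` of the score range times their
    1-based planting index — near-best everywhere, never exactly tied.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = max(3, len(str(cfg.n_compounds)))
    compound_ids = [f"C{i + 1:0{width}d}" for i in range(cfg.n_compounds)]
    n_planted = cfg.n_multitarget if cfg.n_multitarget < cfg.n_compounds else 0
    n_background = cfg.n_compounds - n_planted

    means = np.empty((cfg.n_compounds, len(cfg.targets)))
    for j in range(len(cfg.targets)):
        background = np.minimum(
            rng.normal(cfg.score_mean, cfg.score_sd, size=n_background), -1.0
        )
        means[n_planted:, j] = background
        if n_planted:
            lo, hi = background.min(), background.max()
            margin = cfg.margin_frac * (hi - lo if hi > lo else abs(lo))
            for k in range(n_planted):
                means[k, j] = min(lo + margin * (k + 1), -1.0)

    records = []
    for i, compound in enumerate(compound_ids):
        name = "planted multitarget" if i < n_planted else "background"
        for j, target in enumerate(cfg.targets):
            noise = rng.normal(0.0, cfg.structure_sd, size=cfg.structures_per_target)
            for s in range(cfg.structures_per_target):
                score = min(means[i, j] + noise[s], -1e-3)
                records.append(
                    ScoreRecord(
                        compound_id=compound,
                        compound_name=name,
                        target_id=target,
                        structure_id=f"S{s + 1}",
                        score=float(score),
                    )
                )
    return ScoreTable(records)


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class PlantedApproach:
    """A ligand-residue pair whose distance ramps linearly start -> end.

    The ramp spans the first ``ramp_frac`` of the trajectory and holds at
    ``end`` afterwards (mimicking a ligand settling into a catalytic site
    early in a simulation).
    """

    ligand_atom: str = "C1"
    residue_atom: str = "OG"
    start: float = 4.8
    end: float = 3.0
    ramp_frac: float = 1.0


@dataclass(frozen=True)
class SyntheticTrajectoryConfig:
    """Conditions of a simulated snapshot series.

    A protein-like chain of ``n_residues`` backbone residues (N, CA, C;
    the last residue is a serine carrying an OG side-chain atom) plus a
    ``LIG`` heteroligand, moved rigidly frame to frame and jittered with
    isotropic Gaussian noise of ``noise_sigma`` Angstrom.
    """

    n_residues: int = 20
    n_ligand_atoms: int = 5
    n_frames: int = 31
    dt: float = 100.0
    rotation_deg_per_frame: float = 2.0
    translation_per_frame: float = 0.1
    noise_sigma: float = 0.0
    approach: PlantedApproach | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 2:
            raise ConfigError("n_residues must be >= 2")
        if self.n_ligand_atoms < 1:
            raise ConfigError("n_ligand_atoms must be >= 1")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if self.approach is not None:
            a = self.approach
            if a.start <= 0 or a.end <= 0:
                raise ConfigError("approach distances must be positive")
            if not 0 < a.ramp_frac <= 1:
                raise ConfigError("ramp_frac must lie in (0, 1]")


def _base_structure(cfg: SyntheticTrajectoryConfig, rng: np.random.Generator):
    """Random base coordinates plus the fixed atom identity sequence."""
    identities: list[tuple[str, str, str, int]] = []  # (name, resname, chain, resseq)
    coords: list[np.ndarray] = []
    pos = np.zeros(3)
    for resseq in range(1, cfg.n_residues + 1):
        resname = "SER" if resseq == cfg.n_residues else "ALA"
        pos = pos + rng.normal(0.0, 1.5, size=3) + np.array([3.8, 0.0, 0.0])
        for name in ("N", "CA", "C"):
            coords.append(pos + rng.normal(0.0, 0.8, size=3))
            identities.append((name, resname, "A", resseq))
        if resname == "SER":
            og = coords[-2] + np.array([0.0, 1.4, 0.0])  # branch off CA
            coords.append(og)
            identities.append(("OG", "SER", "A", resseq))
    og_index = len(coords) - 1
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    start = cfg.approach.start if cfg.approach else 4.8
    anchor = coords[og_index] + direction * start
    for k in range(cfg.n_ligand_atoms):
        offset = np.zeros(3) if k == 0 else rng.normal(0.0, 1.0, size=3)
        coords.append(anchor + offset)
        identities.append((f"C{k + 1}", "LIG", "L", 1))
    return np.array(coords), identities, og_index


def simulate_trajectory(cfg: SyntheticTrajectoryConfig) -> Trajectory:
    """Generate a rigid-motion-plus-noise trajectory (seed-deterministic).

    If an approach is planted, the designated ligand-atom/residue-atom
    distance follows the configured linear ramp exactly before noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base, identities, _ = _base_structure(cfg, rng)
    lig_name = cfg.approach.ligand_atom if cfg.approach else "C1"
    res_name = cfg.approach.residue_atom if cfg.approach else "OG"
    try:
        lig_index = next(
            i for i, (name, resname, _, _) in enumerate(identities)
            if resname == "LIG" and name == lig_name
        )
        og_index = next(
            i for i, (name, resname, _, _) in enumerate(identities)
            if resname == "SER" and name == res_name
        )
    except StopIteration:
        raise ConfigError(
            f"approach atoms ({lig_name!r} in LIG, {res_name!r} in SER) not present"
        ) from None
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    drift = rng.normal(size=3)
    drift /= np.linalg.norm(drift)
    base_dir = base[lig_index] - base[og_index]
    base_dir /= np.linalg.norm(base_dir)

    ramp_frames = 1
    if cfg.approach is not None:
        ramp_frames = max(1, round(cfg.approach.ramp_frac * (cfg.n_frames - 1)))

    frames = []
    for k in range(cfg.n_frames):
        rotation = Rotation.from_rotvec(axis * np.deg2rad(k * cfg.rotation_deg_per_frame))
        coords = rotation.apply(base) + k * cfg.translation_per_frame * drift
        if cfg.approach is not None:
            a = cfg.approach
            frac = min(1.0, k / ramp_frames)
            distance = a.start + (a.end - a.start) * frac
            coords[lig_index] = coords[og_index] + rotation.apply(base_dir) * distance
        if cfg.noise_sigma > 0:
            coords = coords + rng.normal(0.0, cfg.noise_sigma, size=coords.shape)
        atoms = [
            AtomRecord(
                serial=i + 1,
                name=name,
                resname=resname,
                chain=chain,
                resseq=resseq,
                element=_ELEMENT_BY_NAME.get(name, name[0]),
                xyz=tuple(float(v) for v in coords[i]),
            )
            for i, (name, resname, chain, resseq) in enumerate(identities)
        ]
        frames.append(Frame(atoms=atoms))
    return Trajectory(frames=frames, dt=cfg.dt)
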