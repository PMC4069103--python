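"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here with explicit
seeds, so that each statistic can be validated against a planted truth:

* trajectories whose domains either fluctuate stationarily about the
  reference (stable) or additionally translate coherently at a constant
  rate (drift — the "ascending RMSD" signature of a destabilized domain);
* labeled multiple alignments with a conserved background and planted
  subfamily-specific columns (distinct consensus residue per subfamily);
* first-order decay and Michaelis–Menten datasets with Gaussian noise;
* minimal donor–H–acceptor triads whose geometry satisfies the H-bond
  criteria in a Bernoulli subset of frames.

Defaults mirror the bookkeeping of a production analysis — 2000 frames at
5 ps (a 10 ns window), three replicates per model — at a toy atom count.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import DecayData, MMData
from .ssp import LabeledMSA
from .structio import AtomRecord, DomainPartition, Trajectory

__all__ = [
    "DomainSpec",
    "TrajSynthConfig",
    "MSASynthConfig",
    "KineticsSynthConfig",
    "gen_trajectory",
    "gen_labeled_msa",
    "gen_decay",
    "gen_mm",
    "gen_hbond_frames",
    "gen_replicate_models",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DomainSpec:
    """One synthetic domain: atom count, fluctuation σ (Å) and drift.

    ``drift_rate`` is the coherent translation in Å per frame applied to
    the whole domain along a fixed axis; ``drift_mode`` is "none" or
    "linear".
    """

    n_atoms: int = 50
    sigma: float = 0.3
    drift_rate: float = 0.0
    drift_mode: str = "none"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.drift_mode not in ("none", "linear"):
            raise ValueError("drift_mode must be 'none' or 'linear'")


@dataclass(frozen=True)
class TrajSynthConfig:
    """Pseudo-trajectory layout: named domains, frames and interval."""

    domains: tuple[tuple[str, DomainSpec], ...] = (
        ("core", DomainSpec()),
        ("B1", DomainSpec()),
    )
    n_frames: int = 2000
    frame_interval: float = 5.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    def partition(self) -> DomainPartition:
        """Residue-range partition matching the generated topology."""
        ranges = {}
        start = 1
        for name, spec in self.domains:
            ranges[name] = [("X", start, start + spec.n_atoms - 1)]
            start += spec.n_atoms
        return DomainPartition(ranges)


def gen_trajectory(config: TrajSynthConfig) -> Trajectory:
    """Generate a pseudo-atom trajectory with per-domain fluctuation/drift.

    Each domain is a spatially separated cluster of one-atom residues
    (chain "X", Cα only).  Atoms fluctuate i.i.d. Gaussian (per-coordinate
    σ) about the frame-0 reference; drifting domains additionally translate
    along +x by drift_rate · frame_index.  With σ = 0 and no drift every
    frame equals the reference.
    """
    rng = np.random.default_rng(config.seed)
    topology: list[AtomRecord] = []
    ref_blocks: list[np.ndarray] = []
    resnum = 1
    for d_index, (name, spec) in enumerate(config.domains):
        # well-separated random cluster per domain
        center = np.array([100.0 * d_index, 0.0, 0.0])
        coords = center + rng.uniform(-10.0, 10.0, size=(spec.n_atoms, 3))
        ref_blocks.append(coords)
        for _ in range(spec.n_atoms):
            topology.append(
                AtomRecord(
                    chain_label="X",
                    residue_number=resnum,
                    residue_name="GLY",
                    atom_name="CA",
                    element="C",
                )
            )
            resnum += 1
    reference = np.concatenate(ref_blocks, axis=0)

    frames = np.empty((config.n_frames, reference.shape[0], 3))
    t = np.arange(config.n_frames)
    offset = 0
    frames[:] = reference[None, :, :]
    for name, spec in config.domains:
        sl = slice(offset, offset + spec.n_atoms)
        if spec.sigma > 0:
            frames[:, sl, :] += rng.normal(0.0, spec.sigma, size=(config.n_frames, spec.n_atoms, 3))
        if spec.drift_mode == "linear" and spec.drift_rate != 0.0:
            frames[:, sl, 0] += spec.drift_rate * t[:, None]
        offset += spec.n_atoms
    # frame 0 is the reference structure exactly (fluctuations start at frame 1)
    frames[0] = reference
    return Trajectory(topology, frames, frame_interval=config.frame_interval)


def gen_replicate_models(
    seed: int = 0,
    n_replicates: int = 3,
    n_frames: int = 4000,
    n_atoms: int = 50,
    sigma: float = 0.3,
    drift_rate: float = 0.0005,
    drifting_domain: str = "B1",
) -> tuple[list[Trajectory], list[Trajectory], DomainPartition]:
    """Two-model replicate experiment: stable model vs destabilized model.

    Emulates the paired-condition study design: each model is simulated in
    ``n_replicates`` independent runs of ``n_frames`` frames (default 20 ns
    at 5 ps) with three domains — a ``core`` anchor used as the
    superposition reference, the nominated ``drifting_domain`` which in
    model 2 translates coherently at ``drift_rate`` Å/frame (0.1 Å/ns at
    the default; ~1 Å accumulated before the trailing 10 ns analysis
    window opens), and a stable control domain ``B2``.  Model 1 has no
    drift anywhere.  Returns (model1 runs, model2 runs, partition); all
    replicate seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_replicates)]

    def build(drifting: bool, seeds: Sequence[int]) -> tuple[list[Trajectory], DomainPartition]:
        trajs = []
        part = None
        for s in seeds:
            cfg = TrajSynthConfig(
                domains=(
                    ("core", DomainSpec(n_atoms, sigma)),
                    (
                        drifting_domain,
                        DomainSpec(
                            n_atoms,
                            sigma,
                            drift_rate if drifting else 0.0,
                            "linear" if drifting else "none",
                        ),
                    ),
                    ("B2", DomainSpec(n_atoms, sigma)),
                ),
                n_frames=n_frames,
                seed=s,
            )
            part = cfg.partition()
            trajs.append(gen_trajectory(cfg))
        return trajs, part

    model1, partition = build(False, child_seeds[:n_replicates])
    model2, _ = build(True, child_seeds[n_replicates:])
    return model1, model2, partition


@dataclass(frozen=True)
class MSASynthConfig:
    """Planted-SSP alignment: conserved background + subfamily columns.

    Background columns share one consensus residue across all subfamilies;
    planted columns carry a distinct consensus per subfamily.  Every
    position is independently replaced by a random other residue with
    probability ``noise_rate``.
    """

    n_subfamilies: int = 4
    sequences_per_subfamily: tuple[int, ...] | int = (20, 10, 10, 4)
    alignment_length: int = 100
    n_planted: int = 3
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted >= self.alignment_length:
            raise ValueError("planted column count must be < alignment length")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must be in [0, 1]")
        sizes = self.sizes()
        if len(sizes) != self.n_subfamilies:
            raise ValueError("one size per subfamily required")

    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.sequences_per_subfamily, int):
            return (self.sequences_per_subfamily,) * self.n_subfamilies
        return tuple(self.sequences_per_subfamily)


def gen_labeled_msa(config: MSASynthConfig) -> tuple[LabeledMSA, list[int]]:
    """Generate a labeled MSA with planted SSP columns.

    Returns (msa, planted_column_indices).  The template is the first
    sequence of the first subfamily; no gaps are generated, so every column
    maps to a template residue number.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes()
    length = config.alignment_length
    planted = sorted(
        rng.choice(length, size=config.n_planted, replace=False).tolist()
    )
    aa = np.array(list(_AMINO_ACIDS))

    background = rng.choice(aa, size=length)
    per_subfamily_consensus: dict[int, np.ndarray] = {}
    for col in planted:
        # distinct residue per subfamily at a planted column
        choices = rng.choice(aa, size=config.n_subfamilies, replace=False)
        per_subfamily_consensus[col] = choices

    ids, seqs, labels = [], [], []
    for sf in range(config.n_subfamilies):
        consensus = background.copy()
        for col in planted:
            consensus[col] = per_subfamily_consensus[col][sf]
        for k in range(sizes[sf]):
            seq = consensus.copy()
            noise_mask = rng.random(length) < config.noise_rate
            if noise_mask.any():
                replacements = rng.choice(aa, size=noise_mask.sum())
                seq[noise_mask] = replacements
            ids.append(f"sf{sf + 1}_seq{k + 1}")
            seqs.append("".join(seq))
            labels.append(f"SF{sf + 1}")
    msa = LabeledMSA(
        ids=ids,
        sequences=seqs,
        labels=labels,
        template_id=ids[0],
        template_chain="B",
        template_start=1,
    )
    return msa, planted


@dataclass(frozen=True)
class KineticsSynthConfig:
    """Generating parameters for decay / Michaelis–Menten data.

    ``noise_sigma`` is Gaussian noise expressed as a fraction of the signal
    scale (A₀ for decay, V_max for rate data); negative draws are truncated
    at zero.
    """

    k_in: float = 0.0026  # min^-1
    a0: float = 100.0
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 601, 30))
    k_cat: float = 25.0  # s^-1
    k_m: float = 25.0  # µM
    e0: float = 1.0  # µM
    substrate_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def gen_decay(config: KineticsSynthConfig) -> DecayData:
    """Exponential decay A₀·exp(−k_in·t) plus truncated Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    a = config.a0 * np.exp(-config.k_in * t)
    if config.noise_sigma > 0:
        a = a + rng.normal(0.0, config.noise_sigma * config.a0, size=t.size)
        a = np.clip(a, 0.0, None)
    return DecayData(times=t, activities=a)


def gen_mm(config: KineticsSynthConfig) -> MMData:
    """Michaelis–Menten initial rates plus truncated Gaussian noise.

    Rate noise is relative (σ = noise_sigma × the true rate at each point),
    matching the roughly constant relative error of initial-rate estimates
    from absorbance traces.
    """
    rng = np.random.default_rng(config.seed)
    s = np.asarray(config.substrate_grid, dtype=float)
    vmax = config.k_cat * config.e0
    v = vmax * s / (config.k_m + s)
    if config.noise_sigma > 0:
        v = v * (1.0 + rng.normal(0.0, config.noise_sigma, size=s.size))
        v = np.clip(v, 0.0, None)
    return MMData(substrate_concentrations=s, initial_rates=v, enzyme_concentration=config.e0)


def gen_hbond_frames(p_bonded: float, n_frames: int, seed: int = 0) -> Trajectory:
    """Minimal donor–H–acceptor triad H-bonded in a Bernoulli(p) frame subset.

    Conforming frames place the acceptor at 2.9 Å donor–acceptor distance
    and 165° D–H–A angle; non-conforming frames stretch the same direction
    to a 4.5 Å donor–acceptor distance (angle unchanged).
    """
    if not 0.0 <= p_bonded <= 1.0:
        raise ValueError("p_bonded must be in [0, 1]")
    rng = np.random.default_rng(seed)
    topology = [
        AtomRecord("A", 1, "SER", "OG", "O"),
        AtomRecord("A", 1, "SER", "HG", "H"),
        AtomRecord("A", 2, "GLU", "OE1", "O"),
    ]
    donor = np.zeros(3)
    hydrogen = np.array([1.0, 0.0, 0.0])

    def acceptor_at(d_da: float) -> np.ndarray:
        # direction from H making a 165 degree D-H-A angle, in the xy plane
        phi = np.radians(180.0 - 165.0)
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        # solve |donor - (hydrogen + L u)| = d_da for L > 0
        w = hydrogen - donor
        b = 2.0 * float(np.dot(w, u))
        c = float(np.dot(w, w)) - d_da**2
        L = (-b + np.sqrt(b * b - 4.0 * c)) / 2.0
        return hydrogen + L * u

    near = acceptor_at(2.9)
    far = acceptor_at(4.5)
    bonded = rng.random(n_frames) < p_bonded
    frames = np.empty((n_frames, 3, 3))
    frames[:, 0, :] = donor
    frames[:, 1, :] = hydrogen
    frames[:, 2, :] = np.where(bonded[:, None], near[None, :], far[None, :])
    return Trajectory(topology, frames, frame_interval=5.0)
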