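"""Near-to-attack conformation (NAC) analysis.

The productive binding mode of an amide substrate in the penicillin-acylase
active site is scored per frame by three distance criteria, all bounded by
3.5 Å (inclusive — a distance exactly at the threshold is productive):

* nucleophile attack geometry: catalytic Ser Oγ ↔ substrate carbonyl C;
* oxyanion-hole backbone contact: substrate carbonyl O ↔ backbone amide N
  (Alaβ69 in the wild-type enzyme);
* oxyanion-hole side-chain contact: substrate carbonyl O ↔ side-chain amide
  N (Asnβ241).

A frame is a NAC iff all three hold; the NAC fraction of a trajectory window
(by convention the last 1000 frames, i.e. 5 ns at a 5 ps save interval) is
the percentage of NAC frames, and replicate runs are summarised as
mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structio import AtomRecord, Trajectory

__all__ = [
    "AtomSpec",
    "NACCriteria",
    "NACResult",
    "nac_check",
    "nac_fraction",
    "nac_replicate_summary",
]


@dataclass(frozen=True)
class AtomSpec:
    """A single named atom: (chain, residue number, atom name)."""

    chain_label: str
    residue_number: int
    atom_name: str

    def resolve(self, topology: Sequence[AtomRecord]) -> int:
        for i, a in enumerate(topology):
            if (
                a.chain_label == self.chain_label
                and a.residue_number == self.residue_number
                and a.atom_name == self.atom_name
            ):
                return i
        raise KeyError(
            f"atom {self.atom_name} of {self.chain_label}{self.residue_number} "
            f"not found in topology"
        )


@dataclass(frozen=True)
class NACCriteria:
    """Three distance constraints defining the productive binding mode.

    Each constraint is (atom_a, atom_b, max_distance Å).  Substrate atom
    names vary between substrates, so they are part of the configuration;
    enzyme-side defaults follow the catalytic machinery (Ser Oγ = "OG",
    backbone N = "N", Asn side-chain amide N = "ND2").
    """

    ser_og: AtomSpec
    substrate_carbonyl_c: AtomSpec
    substrate_carbonyl_o: AtomSpec
    oxyanion_backbone_n: AtomSpec
    oxyanion_sidechain_n: AtomSpec
    max_distance: float = 3.5

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("distance threshold must be > 0")

    def pairs(self) -> list[tuple[AtomSpec, AtomSpec]]:
        return [
            (self.ser_og, self.substrate_carbonyl_c),
            (self.substrate_carbonyl_o, self.oxyanion_backbone_n),
            (self.substrate_carbonyl_o, self.oxyanion_sidechain_n),
        ]


@dataclass
class NACResult:
    """Replicate NAC fractions (%) and their mean ± sample SD."""

    fractions: list[float]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not all(0.0 <= f <= 100.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 100]")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def nac_check(
    frame_coords: np.ndarray,
    topology: Sequence[AtomRecord],
    criteria: NACCriteria,
) -> bool:
    """True iff all three NAC distances do not exceed their threshold."""
    coords = np.asarray(frame_coords, dtype=float)
    for spec_a, spec_b in criteria.pairs():
        ia, ib = spec_a.resolve(topology), spec_b.resolve(topology)
        if np.linalg.norm(coords[ia] - coords[ib]) > criteria.max_distance:
            return False
    return True


def nac_fraction(
    traj: Trajectory,
    criteria: NACCriteria,
    frame_window: tuple[int, int] | None = None,
) -> float:
    """Percentage of window frames in the near-to-attack conformation.

    Default window: the last min(1000, n_frames) frames.
    """
    if frame_window is None:
        start = max(0, traj.n_frames - 1000)
        frame_window = (start, traj.n_frames)
    start, stop = frame_window
    if not (0 <= start < stop <= traj.n_frames):
        raise ValueError(f"invalid frame window ({start}, {stop})")
    # resolve atom indices once; per-frame check is then pure arithmetic
    idx_pairs = [
        (a.resolve(traj.topology), b.resolve(traj.topology)) for a, b in criteria.pairs()
    ]
    window = traj.frames[start:stop]
    ok = np.ones(stop - start, dtype=bool)
    for ia, ib in idx_pairs:
        d = np.linalg.norm(window[:, ia, :] - window[:, ib, :], axis=1)
        ok &= d <= criteria.max_distance
    return 100.0 * float(np.count_nonzero(ok)) / (stop - start)


def nac_replicate_summary(fractions: Sequence[float]) -> NACResult:
    """Mean ± sample SD (n−1) of replicate NAC percentages."""
    if len(fractions) < 2:
        raise ValueError("sample SD requires >= 2 replicates")
    arr = np.asarray(fractions, dtype=float)
    return NACResult(
        fractions=list(map(float, arr)),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
    )
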