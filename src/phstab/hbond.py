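"""Geometric hydrogen-bond detection, persistence and network comparison.

A hydrogen bond is accepted when the donor–acceptor distance is at most
3.5 Å and the donor–hydrogen–acceptor angle lies in 145°–180° (inclusive
boundaries).  Donors are N/O/S heavy atoms with a covalently attached
hydrogen (attachment inferred from geometry: H within 1.25 Å); acceptors are
N/O/S atoms; water oxygens act as both.  When a structure carries no
hydrogens at all (crystal structures screened before protonation), a
heavy-atom fallback mode accepts on donor–acceptor distance alone and flags
the result.

Per-residue-pair persistence over a trajectory window and residue-level
interaction networks (including water bridges, as for the buried water
linking the two β-sheets of the αββα core) are built on top of per-frame
detection; networks are plain :mod:`networkx` graphs keyed by residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structio import AtomRecord, Selection, Trajectory

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondNetwork",
    "PersistenceReport",
    "detect_hbonds",
    "hbond_persistence",
    "extract_network",
    "diff_networks",
]

_DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "S"})
_H_COVALENT_CUTOFF = 1.25  # Å; X–H covalent bond upper bound
_WATER_NAMES = frozenset({"HOH", "WAT"})

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance window for a hydrogen bond."""

    max_donor_acceptor_distance: float = 3.5  # Å
    dha_angle_range: tuple[float, float] = (145.0, 180.0)  # degrees

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        lo, hi = self.dha_angle_range
        if not (0 <= lo <= hi <= 180):
            raise ValueError("angle range must satisfy 0 <= min <= max <= 180")


@dataclass(frozen=True)
class HBond:
    """One accepted donor–hydrogen–acceptor contact (atom indices + geometry)."""

    donor_index: int
    hydrogen_index: int | None  # None in heavy-atom fallback mode
    acceptor_index: int
    distance: float  # donor–acceptor, Å
    angle: float | None  # D–H–A, degrees; None in fallback mode


@dataclass
class HBondNetwork:
    """Residue-level H-bond graph for one frame."""

    graph: nx.Graph
    frame_index: int = 0
    heavy_atom_mode: bool = False

    @property
    def nodes(self) -> set[ResidueKey]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, node: ResidueKey) -> int:
        return self.graph.degree[node]


@dataclass
class PersistenceReport:
    """Fraction of frames in which each residue pair forms a qualifying bond."""

    fractions: dict[tuple[ResidueKey, ResidueKey], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"persistence for {pair} outside [0, 1]: {frac}")


def _classify_atoms(
    topology: Sequence[AtomRecord], coords: np.ndarray
) -> tuple[list[tuple[int, int]], list[int], bool]:
    """Find (donor heavy atom, attached H) pairs and acceptor atoms.

    Returns (donor_h_pairs, acceptor_indices, has_hydrogens).
    """
    heavy = [
        i for i, a in enumerate(topology) if a.element.upper() in _DONOR_ACCEPTOR_ELEMENTS
    ]
    hydrogens = [i for i, a in enumerate(topology) if a.element.upper() == "H"]
    donor_pairs: list[tuple[int, int]] = []
    if hydrogens and heavy:
        tree = cKDTree(coords[heavy])
        for h in hydrogens:
            dist, j = tree.query(coords[h], k=1)
            if dist <= _H_COVALENT_CUTOFF:
                donor_pairs.append((heavy[j], h))
    return donor_pairs, heavy, bool(hydrogens)


def detect_hbonds(
    frame_coords: np.ndarray,
    topology: Sequence[AtomRecord],
    criteria: HBondCriteria = HBondCriteria(),
    donors: Selection | None = None,
    acceptors: Selection | None = None,
    heavy_atom_fallback: bool = False,
) -> list[HBond]:
    """All hydrogen bonds in one frame satisfying both geometric criteria.

    ``donors`` / ``acceptors`` optionally restrict the candidate rosters
    (applied to the donor heavy atom and the acceptor atom).  With
    ``heavy_atom_fallback=True`` a hydrogen-free topology is screened on
    donor–acceptor distance alone (every N/O/S is treated as a potential
    donor); without it such a topology raises an error.
    """
    coords = np.asarray(frame_coords, dtype=float)
    donor_pairs, heavy, has_h = _classify_atoms(topology, coords)

    donor_ok = None if donors is None else set(donors.resolve(topology).tolist())
    acc_ok = None if acceptors is None else set(acceptors.resolve(topology).tolist())
    acceptor_idx = [i for i in heavy if acc_ok is None or i in acc_ok]

    bonds: list[HBond] = []
    if not has_h:
        if not heavy_atom_fallback:
            raise ValueError(
                "topology carries no hydrogens; pass heavy_atom_fallback=True "
                "to screen on donor-acceptor distance alone"
            )
        tree = cKDTree(coords[acceptor_idx]) if acceptor_idx else None
        for d in heavy:
            if donor_ok is not None and d not in donor_ok:
                continue
            for j in tree.query_ball_point(coords[d], criteria.max_donor_acceptor_distance):
                a = acceptor_idx[j]
                if a == d or topology[a].residue_key == topology[d].residue_key:
                    continue
                dist = float(np.linalg.norm(coords[d] - coords[a]))
                bonds.append(HBond(d, None, a, dist, None))
        return bonds

    lo, hi = criteria.dha_angle_range
    tree = cKDTree(coords[acceptor_idx]) if acceptor_idx else None
    for d, h in donor_pairs:
        if donor_ok is not None and d not in donor_ok:
            continue
        if tree is None:
            continue
        for j in tree.query_ball_point(coords[d], criteria.max_donor_acceptor_distance):
            a = acceptor_idx[j]
            if a == d or a == h:
                continue
            if topology[a].residue_key == topology[d].residue_key:
                continue  # no intra-residue bonds
            dist = float(np.linalg.norm(coords[d] - coords[a]))
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if lo <= angle <= hi:
                bonds.append(HBond(d, h, a, dist, angle))
    return bonds


def hbond_persistence(
    traj: Trajectory,
    pair_spec: tuple[ResidueKey, ResidueKey],
    criteria: HBondCriteria = HBondCriteria(),
    frame_window: tuple[int, int] | None = None,
    heavy_atom_fallback: bool = False,
) -> float:
    """Fraction of window frames in which the residue pair is H-bonded.

    ``pair_spec`` is ((donor chain, resnum), (acceptor chain, resnum)); any
    qualifying donor/acceptor atom pair between the two residues counts.
    ``frame_window`` is a half-open (start, stop) frame range, default all.
    """
    donor_res, acceptor_res = pair_spec
    keys = {a.residue_key for a in traj.topology}
    for res in (donor_res, acceptor_res):
        if res not in keys:
            raise KeyError(f"residue {res} not present in topology")
    start, stop = frame_window if frame_window is not None else (0, traj.n_frames)
    if not (0 <= start < stop <= traj.n_frames):
        raise ValueError(f"invalid frame window ({start}, {stop})")
    donors_sel = Selection(ranges=((donor_res[0], donor_res[1], donor_res[1]),))
    acc_sel = Selection(ranges=((acceptor_res[0], acceptor_res[1], acceptor_res[1]),))
    hits = 0
    for i in range(start, stop):
        bonds = detect_hbonds(
            traj.frames[i],
            traj.topology,
            criteria,
            donors=donors_sel,
            acceptors=acc_sel,
            heavy_atom_fallback=heavy_atom_fallback,
        )
        if any(
            traj.topology[b.donor_index].residue_key == donor_res
            and traj.topology[b.acceptor_index].residue_key == acceptor_res
            for b in bonds
        ):
            hits += 1
    return hits / (stop - start)


def _is_water(atom: AtomRecord) -> bool:
    return atom.residue_name in _WATER_NAMES


def extract_network(
    frame_coords: np.ndarray,
    topology: Sequence[AtomRecord],
    criteria: HBondCriteria = HBondCriteria(),
    seed_residues: Iterable[ResidueKey] = (),
    include_waters: bool = True,
    frame_index: int = 0,
    heavy_atom_fallback: bool = False,
) -> HBondNetwork:
    """Residue-level H-bond network around a set of seed residues.

    The network contains all bonds among the seeds and their direct
    partners; with ``include_waters`` every water reached this way also
    contributes its remaining bonds (one water hop), so a buried bridging
    water appears with its full degree.
    """
    seeds = set(seed_residues)
    keys = {a.residue_key for a in topology}
    missing = seeds - keys
    if missing:
        raise KeyError(f"seed residues not in topology: {sorted(missing)}")

    has_h = any(a.element.upper() == "H" for a in topology)
    bonds = detect_hbonds(
        np.asarray(frame_coords, dtype=float),
        topology,
        criteria,
        heavy_atom_fallback=heavy_atom_fallback,
    )
    full = nx.Graph()
    for b in bonds:
        u = topology[b.donor_index].residue_key
        v = topology[b.acceptor_index].residue_key
        if u != v:
            full.add_edge(u, v, distance=b.distance, angle=b.angle)

    node_set: set[ResidueKey] = set(seeds)
    for s in seeds:
        if s in full:
            node_set.update(full.neighbors(s))
    if include_waters:
        water_keys = {a.residue_key for a in topology if _is_water(a)}
        waters = node_set & water_keys
        for w in waters:
            if w in full:
                node_set.update(full.neighbors(w))

    sub = nx.Graph()
    sub.add_nodes_from(seeds)
    for u, v, data in full.subgraph(node_set).edges(data=True):
        sub.add_edge(u, v, **data)
    # keep only edge endpoints plus (possibly isolated) seeds
    for n in list(sub.nodes):
        if sub.degree[n] == 0 and n not in seeds:
            sub.remove_node(n)
    return HBondNetwork(graph=sub, frame_index=frame_index, heavy_atom_mode=not has_h)


def diff_networks(
    net_a: HBondNetwork, net_b: HBondNetwork
) -> tuple[set[frozenset], set[frozenset], set[frozenset]]:
    """(shared, lost, gained) residue-pair edges going from net_a to net_b."""
    ea, eb = net_a.edges, net_b.edges
    return ea & eb, ea - eb, eb - ea
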