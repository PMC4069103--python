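"""Structure and trajectory handling.

The structural statistics in this package all operate on a light-weight
:class:`Trajectory`: a fixed atom roster (topology) plus an ordered stack of
coordinate frames in Å, saved at a constant time interval in ps.  Multi-model
PDB files (MODEL/ENDMDL blocks) are the on-disk representation, so that any
MD package able to export PDB snapshots can feed the pipeline; crystal waters
and ions are ordinary atoms here and are preserved on input and output.

Domains of the penicillin-acylase heterodimer (A1, A2, B1-1/2/3, B2, B3) are
expressed as :class:`DomainPartition` — named lists of inclusive per-chain
residue ranges — and all RMSD/RMSF statistics accept arbitrary
:class:`Selection` filters (chain, residue ranges, atom names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Trajectory",
    "DomainPartition",
    "Selection",
    "SuperpositionResult",
    "RMSDSeries",
    "RMSFProfile",
    "PDBFormatError",
    "BACKBONE_ATOMS",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "domain_residue_count",
]

#: Protein backbone heavy atoms (N, Cα, carbonyl C and O).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class PDBFormatError(ValueError):
    """Raised for structurally invalid multi-model PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology.

    Residue numbering is 1-based per chain; the α/β chains of the
    penicillin-acylase heterodimer map to PDB chains ``A`` and ``B``.
    Crystal waters (``HOH``) and ions (e.g. ``CA``) are plain records.
    """

    chain_label: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_label, self.residue_number)


class Trajectory:
    """Shared topology + ordered coordinate frames (Å) at fixed interval (ps)."""

    def __init__(
        self,
        topology: Sequence[AtomRecord],
        frames: np.ndarray | Sequence[np.ndarray],
        frame_interval: float = 5.0,
    ) -> None:
        self.topology = list(topology)
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != len(self.topology):
            raise ValueError(
                f"each frame must have one position per topology atom: "
                f"got {frames.shape[1]} positions for {len(self.topology)} atoms"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame coordinates must be finite")
        if frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.frames = frames
        self.frame_interval = float(frame_interval)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def frame_times(self) -> np.ndarray:
        """Time of each frame in ps (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class DomainPartition:
    """Named domains as inclusive per-chain residue ranges.

    ``domains`` maps a domain name to a list of ``(chain_label, start, end)``
    tuples, e.g. the catalytic αββα core split over three sequence segments::

        DomainPartition({"B1": [("B", 1, 72), ("B", 146, 290), ("B", 452, 536)]})
    """

    domains: Mapping[str, Sequence[tuple[str, int, int]]]

    def __post_init__(self) -> None:
        for name, ranges in self.domains.items():
            seen: dict[str, list[tuple[int, int]]] = {}
            for chain, start, end in ranges:
                if start > end:
                    raise ValueError(
                        f"domain {name!r}: range start {start} > end {end}"
                    )
                for s, e in seen.get(chain, []):
                    if start <= e and s <= end:
                        raise ValueError(
                            f"domain {name!r}: overlapping ranges on chain {chain}"
                        )
                seen.setdefault(chain, []).append((start, end))

    def names(self) -> list[str]:
        return list(self.domains)

    def selection(self, domain_name: str, atom_names: Iterable[str] | None = None) -> "Selection":
        """Selection covering one domain, optionally restricted by atom name."""
        if domain_name not in self.domains:
            raise KeyError(f"unknown domain {domain_name!r}")
        return Selection(
            ranges=tuple(self.domains[domain_name]),
            atom_names=frozenset(atom_names) if atom_names is not None else None,
        )


@dataclass(frozen=True)
class Selection:
    """Atom filter: chain/residue ranges and/or an atom-name set.

    A ``None`` field means "no constraint".  Resolution against a topology is
    deterministic and preserves topology order.
    """

    chains: frozenset[str] | None = None
    ranges: tuple[tuple[str, int, int], ...] | None = None
    atom_names: frozenset[str] | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_label not in self.chains:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.ranges is not None:
            return any(
                atom.chain_label == chain and start <= atom.residue_number <= end
                for chain, start, end in self.ranges
            )
        return True

    def resolve(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        """Indices of matching atoms, in topology order."""
        idx = [i for i, atom in enumerate(topology) if self.matches(atom)]
        return np.asarray(idx, dtype=int)


def backbone_selection(ranges: Sequence[tuple[str, int, int]] | None = None) -> Selection:
    """Backbone-atom selection ({N, CA, C, O}), optionally range-restricted."""
    return Selection(
        ranges=tuple(ranges) if ranges is not None else None,
        atom_names=BACKBONE_ATOMS,
    )


def calpha_selection(ranges: Sequence[tuple[str, int, int]] | None = None) -> Selection:
    """Cα-only selection, optionally range-restricted."""
    return Selection(
        ranges=tuple(ranges) if ranges is not None else None,
        atom_names=frozenset({"CA"}),
    )


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform (proper rotation + translation) and the attained RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSeries:
    """Per-frame RMSD (Å) with frame times (ps) and an identifying label."""

    values: np.ndarray
    frame_times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have equal length")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RMSFProfile:
    """Per-residue Cα fluctuation (Å), keyed by (chain_label, residue_number)."""

    values: dict[tuple[str, int], float] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.values[key]

    def items(self):
        return self.values.items()


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _roster_key(atom) -> tuple[str, int, str, str]:
    return (atom.chain_label, atom.residue_number, atom.residue_name, atom.atom_name)


def read_multimodel_pdb(path) -> Trajectory:
    """Read a multi-model PDB file as a Trajectory (one frame per MODEL).

    All MODEL blocks must share one atom roster (same chains, residues and
    atom names in the same order); HETATM records — crystal waters, ions,
    bound substrates — are retained.  Single-model files yield a one-frame
    trajectory.  The frame interval is not stored in PDB; the default 5 ps
    is attached and can be overridden on the returned object.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no MODEL blocks / atoms found")

    topology: list[AtomRecord] = []
    frames: list[list[tuple[float, float, float]]] = []
    ref_roster: list[tuple[str, int, str, str]] | None = None
    for i_model, model in enumerate(st, start=1):
        roster: list[tuple[str, int, str, str]] = []
        coords: list[tuple[float, float, float]] = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    roster.append(
                        (chain.name, residue.seqid.num, residue.name, atom.name)
                    )
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    if ref_roster is None:
                        topology.append(
                            AtomRecord(
                                chain_label=chain.name,
                                residue_number=residue.seqid.num,
                                residue_name=residue.name,
                                atom_name=atom.name,
                                element=atom.element.name,
                            )
                        )
        if ref_roster is None:
            ref_roster = roster
        elif roster != ref_roster:
            raise PDBFormatError(
                f"{path}: model {i_model} atom roster differs from model 1"
            )
        frames.append(coords)

    return Trajectory(topology, np.asarray(frames, dtype=float))


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a standard multi-model PDB (MODEL/ENDMDL).

    A MODEL/ENDMDL pair is emitted even for single-frame trajectories so that
    the frame structure survives a read/write round trip.
    """
    import gemmi

    if traj.n_frames == 0:
        raise ValueError("no frames to write")

    st = gemmi.Structure()
    st.name = "phstab"
    for i_frame in range(traj.n_frames):
        model = gemmi.Model(i_frame + 1)
        # build chains/residues fully before adding them: gemmi's add_* copy
        chain: gemmi.Chain | None = None
        residue: gemmi.Residue | None = None
        prev_chain_label: str | None = None
        prev_res_key: tuple[int, str] | None = None

        def flush_residue() -> None:
            nonlocal residue
            if residue is not None:
                chain.add_residue(residue)
                residue = None

        def flush_chain() -> None:
            nonlocal chain
            flush_residue()
            if chain is not None:
                model.add_chain(chain)
                chain = None

        for atom_rec, pos in zip(traj.topology, traj.frames[i_frame]):
            if atom_rec.chain_label != prev_chain_label:
                flush_chain()
                chain = gemmi.Chain(atom_rec.chain_label)
                prev_chain_label = atom_rec.chain_label
                prev_res_key = None
            res_key = (atom_rec.residue_number, atom_rec.residue_name)
            if res_key != prev_res_key:
                flush_residue()
                residue = gemmi.Residue()
                residue.name = atom_rec.residue_name
                residue.seqid = gemmi.SeqId(atom_rec.residue_number, " ")
                prev_res_key = res_key
            atom = gemmi.Atom()
            atom.name = atom_rec.atom_name
            atom.element = gemmi.Element(atom_rec.element)
            atom.pos = gemmi.Position(*map(float, pos))
            residue.add_atom(atom)
        flush_chain()
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))

    if traj.n_frames == 1:
        # gemmi omits MODEL/ENDMDL for single-model structures; restore them.
        with open(path) as fh:
            lines = fh.readlines()
        out: list[str] = []
        opened = False
        for line in lines:
            rec = line[:6]
            if not opened and rec in ("ATOM  ", "HETATM"):
                out.append("MODEL        1\n")
                opened = True
            if rec == "END   " or line.strip() == "END":
                if opened:
                    out.append("ENDMDL\n")
                    opened = False
            out.append(line)
        if opened:
            out.append("ENDMDL\n")
        with open(path, "w") as fh:
            fh.writelines(out)


# ---------------------------------------------------------------------------
# Superposition and trajectory statistics
# ---------------------------------------------------------------------------

def superpose(mobile_coords: np.ndarray, reference_coords: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body fit of mobile onto reference coordinates.

    Returns the proper rotation (det = +1) and translation minimizing the
    RMSD between the transformed mobile points and the reference, together
    with that minimal RMSD.  Requires n >= 3 non-collinear paired points.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = mob.shape[0]
    if n < 3:
        raise ValueError(f"superposition requires >= 3 points, got {n}")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    # collinearity check: rank of the centered mobile set
    if np.linalg.matrix_rank(mob0, tol=1e-9) < 2 or np.linalg.matrix_rank(ref0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(ref0, mob0)
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mob_c
    fitted = mob @ matrix.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=rmsd)


def _coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    measure_selection: Selection,
    fit_selection: Selection | None = None,
    reference_frame: int = 0,
    label: str = "",
) -> RMSDSeries:
    """Per-frame RMSD (Å) of ``measure_selection`` after a rigid fit.

    Each frame is superposed onto the reference frame using
    ``fit_selection`` (defaults to the measured selection itself — a local,
    per-domain fit that isolates internal deformation; pass a wider or
    external selection for a global fit) and the RMSD is then evaluated over
    ``measure_selection``.
    """
    if fit_selection is None:
        fit_selection = measure_selection
    meas_idx = measure_selection.resolve(traj.topology)
    fit_idx = fit_selection.resolve(traj.topology)
    if len(meas_idx) == 0 or len(fit_idx) < 3:
        raise ValueError("selections must resolve to >= 1 measured and >= 3 fit atoms")
    ref = traj.frames[reference_frame]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        fit = superpose(traj.frames[i][fit_idx], ref[fit_idx])
        moved = fit.apply(traj.frames[i][meas_idx])
        values[i] = _coord_rmsd(moved, ref[meas_idx])
    return RMSDSeries(values=values, frame_times=traj.frame_times(), label=label)


def rmsf_profile(
    traj: Trajectory,
    ca_selection: Selection | None = None,
    window_frames: int | None = None,
) -> RMSFProfile:
    """Per-residue Cα RMSF (Å) about the mean structure of a trailing window.

    The last ``window_frames`` frames (default: min(2000, all) — 10 ns at the
    5 ps save interval) are aligned to the first frame of the window on the
    Cα selection; the RMSF of atom i is sqrt(mean_t |x_i(t) − <x_i>|²).
    """
    if ca_selection is None:
        ca_selection = calpha_selection()
    idx = ca_selection.resolve(traj.topology)
    if len(idx) < 3:
        raise ValueError("Cα selection must resolve to >= 3 atoms")
    if window_frames is None:
        window_frames = min(2000, traj.n_frames)
    if window_frames > traj.n_frames:
        raise ValueError(
            f"window of {window_frames} frames exceeds trajectory length {traj.n_frames}"
        )
    window = traj.frames[traj.n_frames - window_frames :, idx, :]
    aligned = np.empty_like(window)
    ref = window[0]
    for i in range(window.shape[0]):
        aligned[i] = superpose(window[i], ref).apply(window[i])
    mean_structure = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean_structure) ** 2, axis=2), axis=0))
    profile = RMSFProfile()
    for j, atom_i in enumerate(idx):
        atom = traj.topology[atom_i]
        profile.values[atom.residue_key] = float(rmsf[j])
    return profile


def domain_residue_count(partition: DomainPartition, domain_name: str) -> int:
    """Number of residues in a named domain: Σ (end − start + 1) over ranges."""
    if domain_name not in partition.domains:
        raise KeyError(f"unknown domain {domain_name!r}")
    return sum(end - start + 1 for _, start, end in partition.domains[domain_name])
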