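"""Protonation-state assignment from per-residue pKa values.

Constant-protonation MD treats pH by fixing the ionization state of every
titratable group before the simulation: a residue is protonated iff its
predicted pKa is strictly greater than the target pH.  pKa prediction itself
(PROPKA or similar) is upstream of this package — pKa values arrive as a
plain-text table — but a fallback table of textbook model pKas is provided
for quick screening.  Manual overrides (e.g. forcing the catalytic Ser's
N-terminal amine deprotonated at any pH, or pinning a carboxyl-carboxylate
partner's state per pH) take precedence over the rule and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .structio import AtomRecord

__all__ = [
    "PKaTable",
    "ProtonationDecision",
    "OverrideRule",
    "MODEL_PKAS",
    "PROTON_TARGET_ATOMS",
    "assign_protonation",
    "default_model_pkas",
    "read_pka_table",
]

logger = logging.getLogger(__name__)

#: Textbook model pKa values per titratable group. N-/C-termini are keyed by
#: the pseudo-residue names NTR/CTR.
MODEL_PKAS: dict[str, float] = {
    "ASP": 3.8,
    "GLU": 4.2,
    "HIS": 6.0,
    "LYS": 10.5,
    "ARG": 12.5,
    "CYS": 8.3,
    "TYR": 10.1,
    "NTR": 8.0,
    "CTR": 3.5,
}

#: Heavy atom that receives the proton when a group is protonated.
PROTON_TARGET_ATOMS: dict[str, str] = {
    "ASP": "OD",
    "GLU": "OE",
    "LYS": "NZ",
    "ARG": "NE",
    "HIS": "NE2",  # default tautomer; doubly protonated His adds ND1
    "CYS": "SG",
    "TYR": "OH",
    "NTR": "N",
    "CTR": "O",
}

ResidueKey = tuple[str, int, str]  # (chain_label, residue_number, residue_name)


@dataclass
class PKaTable:
    """Map (chain, residue number, residue name) -> pKa."""

    entries: dict[ResidueKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, pka in self.entries.items():
            if not (pka == pka and abs(pka) != float("inf")):
                raise ValueError(f"non-finite pKa for {key}")

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class ProtonationDecision:
    """State assigned to one titratable group, with its provenance."""

    residue: ResidueKey
    state: str  # "protonated" | "deprotonated"
    proton_target_atom: str | None
    source: str  # "rule" | "override"
    pka: float | None = None

    def __post_init__(self) -> None:
        if self.state not in ("protonated", "deprotonated"):
            raise ValueError(f"invalid state {self.state!r}")


@dataclass(frozen=True)
class OverrideRule:
    """Forced state for one residue, either at a specific pH or at any pH.

    ``ph`` is a float to apply the override at that pH only, or the string
    ``"any"`` for a pH-independent override.
    """

    chain_label: str
    residue_number: int
    residue_name: str
    state: str
    ph: float | str = "any"

    @property
    def residue(self) -> ResidueKey:
        return (self.chain_label, self.residue_number, self.residue_name)

    def applies_at(self, target_ph: float) -> bool:
        if self.ph == "any":
            return True
        return abs(float(self.ph) - target_ph) < 1e-9


def assign_protonation(
    pka_table: PKaTable,
    target_ph: float,
    overrides: Sequence[OverrideRule] = (),
) -> list[ProtonationDecision]:
    """Assign a protonation state to every entry of the pKa table.

    Rule: protonated iff pKa > target pH (strict; a group whose pKa equals
    the pH is left deprotonated).  Overrides matching the target pH replace
    the rule's decision and are logged.  An override referencing a residue
    absent from the table is an error — it would silently do nothing.
    """
    if not (target_ph == target_ph and abs(target_ph) != float("inf")):
        raise ValueError("target_pH must be finite")
    for rule in overrides:
        if rule.residue not in pka_table.entries:
            raise KeyError(
                f"override references residue {rule.residue} absent from the pKa table"
            )
    forced: dict[ResidueKey, OverrideRule] = {}
    for rule in overrides:
        if rule.applies_at(target_ph):
            forced[rule.residue] = rule

    decisions: list[ProtonationDecision] = []
    for residue, pka in pka_table.items():
        resname = residue[2]
        if residue in forced:
            state = forced[residue].state
            source = "override"
            logger.info(
                "protonation override: %s -> %s at pH %.2f", residue, state, target_ph
            )
        else:
            state = "protonated" if pka > target_ph else "deprotonated"
            source = "rule"
        target_atom = PROTON_TARGET_ATOMS.get(resname) if state == "protonated" else None
        decisions.append(
            ProtonationDecision(
                residue=residue,
                state=state,
                proton_target_atom=target_atom,
                source=source,
                pka=pka,
            )
        )
    return decisions


def default_model_pkas(topology: Iterable[AtomRecord]) -> PKaTable:
    """Model-pKa table for every titratable residue plus chain termini.

    Residues are grouped from the topology; the first and last amino-acid
    residue of each chain contribute NTR/CTR entries.  Waters, ions and
    other non-titratable residues are omitted.
    """
    seen: list[ResidueKey] = []
    seen_set: set[ResidueKey] = set()
    chain_residues: dict[str, list[ResidueKey]] = {}
    for atom in topology:
        key = (atom.chain_label, atom.residue_number, atom.residue_name)
        if key in seen_set:
            continue
        seen_set.add(key)
        seen.append(key)
        if atom.residue_name not in ("HOH", "WAT") and atom.residue_name.isalpha() and len(atom.residue_name) == 3:
            chain_residues.setdefault(atom.chain_label, []).append(key)

    entries: dict[ResidueKey, float] = {}
    for key in seen:
        pka = MODEL_PKAS.get(key[2])
        if pka is not None:
            entries[key] = pka
    for chain, residues in chain_residues.items():
        first, last = residues[0], residues[-1]
        entries[(chain, first[1], "NTR")] = MODEL_PKAS["NTR"]
        entries[(chain, last[1], "CTR")] = MODEL_PKAS["CTR"]
    return PKaTable(entries)


def read_pka_table(path) -> PKaTable:
    """Read a whitespace-delimited pKa file: ``chain resnum resname pKa``."""
    entries: dict[ResidueKey, float] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{i}: expected 'chain resnum resname pKa'")
            chain, resnum, resname, pka = parts
            entries[(chain, int(resnum), resname.upper())] = float(pka)
    return PKaTable(entries)
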