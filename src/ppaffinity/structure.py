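"""Structure model and PDB input/output.

The internal model is deliberately small: a :class:`Structure` is a list of
standard amino-acid residues, each holding heavy atoms, with every chain
tagged as belonging to partner A, partner B, or ignored. Parsing goes
through Bio.PDB; the cleanup rules are fixed for reproducibility:

* hydrogens, waters and hetero-residues are removed (modified residues
  with a standard parent, e.g. MSE, are mapped to it);
* for alternate locations the highest-occupancy conformer is kept, ties
  broken alphabetically by altloc code;
* residues keep their author numbering — the identity key is
  ``(chain_id, seq_id, insertion_code)`` throughout, no renumbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._tables import MODIFIED_PARENT, THREE_TO_ONE, atom_radius

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "Residue", "ResidueID", "Structure", "Gap", "GapReport",
    "load_structure", "write_pdb", "detect_gaps", "parse_partner_spec",
]

#: (chain_id, author seq number, insertion code) — the residue identity key.
ResidueID = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a "
                             "finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    icode: str
    name: str  # 3-letter code, standard amino acid
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> ResidueID:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array(
            [atom_radius(self.name, a.name, a.element) for a in self.atoms])

    def label(self) -> str:
        return f"{self.name} {self.chain_id}{self.seq_id}{self.icode}".strip()


@dataclass
class Structure:
    """Residues grouped by chain, with partner tags.

    ``partner_of`` maps each chain id to ``"A"``, ``"B"`` or ``None``
    (ignored). Partner A and B chain sets must be disjoint and non-empty.
    """

    residues: list[Residue]
    partner_of: dict[str, str | None]
    name: str = ""

    def __post_init__(self) -> None:
        a = self.partner_chains("A")
        b = self.partner_chains("B")
        if a & b:
            raise ValueError(f"partners share chains: {sorted(a & b)}")
        for tag, chains in (("A", a), ("B", b)):
            if not chains:
                raise ValueError(f"partner {tag} has no chains")
            if not any(r.chain_id in chains for r in self.residues):
                raise ValueError(
                    f"partner {tag} (chains {sorted(chains)}) contains no "
                    "standard residues")

    def partner_chains(self, tag: str) -> set[str]:
        return {c for c, t in self.partner_of.items() if t == tag}

    def partner_residues(self, tag: str) -> list[Residue]:
        chains = self.partner_chains(tag)
        return [r for r in self.residues if r.chain_id in chains]

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def tagged_residues(self) -> list[Residue]:
        """Residues of the two partners only, ignored chains excluded."""
        keep = self.partner_chains("A") | self.partner_chains("B")
        return [r for r in self.residues if r.chain_id in keep]

    def __len__(self) -> int:
        return len(self.residues)


def parse_partner_spec(spec: str) -> tuple[set[str], set[str]]:
    """Parse ``"A,B:C"`` into partner chain sets ({A,B}, {C})."""
    try:
        left, right = spec.split(":")
    except ValueError:
        raise ValueError(
            f"partner spec {spec!r} must be of the form 'A,B:C'") from None
    a = {c.strip() for c in left.split(",") if c.strip()}
    b = {c.strip() for c in right.split(",") if c.strip()}
    if not a or not b:
        raise ValueError(f"partner spec {spec!r}: empty partner group")
    return a, b


def _select_altloc(disordered) -> "Bio.PDB.Atom.Atom":  # noqa: F821
    children = disordered.disordered_get_list()
    children = sorted(
        children, key=lambda at: (-(at.get_occupancy() or 0.0), at.get_altloc()))
    return children[0]


def load_structure(
    path: str | Path,
    partner_a: Iterable[str],
    partner_b: Iterable[str],
    name: str | None = None,
) -> Structure:
    """Read a PDB file and tag the two interacting partners.

    Hydrogens, waters and hetero-residues are dropped; modified residues
    with a standard parent are renamed to it; the highest-occupancy
    alternate location is kept. Chains not in either partner group are
    retained but tagged as ignored.

    Raises
    ------
    ValueError
        If a requested chain is absent or a partner ends up with zero
        standard residues.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    partner_a, partner_b = set(partner_a), set(partner_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Bio.PDB is chatty about headers
        model = PDBParser(QUIET=True).get_structure(name or path.stem, path)[0]

    present = {ch.id for ch in model}
    for tag, chains in (("A", partner_a), ("B", partner_b)):
        missing = chains - present
        if missing:
            raise ValueError(
                f"partner {tag}: chain(s) {sorted(missing)} not found in "
                f"{path.name} (available: {sorted(present)})")

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag = res.id[0]
            resname = res.get_resname().strip()
            if hetflag == "W":
                continue
            if resname in MODIFIED_PARENT:
                resname = MODIFIED_PARENT[resname]
            elif hetflag != " ":
                continue  # ligands, ions, nucleic acids
            if resname not in THREE_TO_ONE:
                logger.warning("skipping non-standard residue %s %s%s",
                               resname, chain.id, res.id[1])
                continue
            atoms: list[Atom] = []
            for at in res:  # DisorderedAtom wrappers yield all altlocs
                if at.is_disordered():
                    at = _select_altloc(at)
                element = (at.element or at.get_name()[0]).strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(Atom(
                    name=at.get_name().strip(),
                    element=element,
                    coord=np.asarray(at.get_coord(), dtype=float),
                    occupancy=float(at.get_occupancy() or 1.0),
                    altloc=at.get_altloc().strip(),
                ))
            if atoms:
                residues.append(Residue(
                    chain_id=chain.id,
                    seq_id=int(res.id[1]),
                    icode=res.id[2].strip(),
                    name=resname,
                    atoms=atoms,
                ))

    partner_of: dict[str, str | None] = {}
    for ch in present:
        partner_of[ch] = "A" if ch in partner_a else (
            "B" if ch in partner_b else None)
    return Structure(residues=residues, partner_of=partner_of,
                     name=name or path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as minimal ATOM records (fixture round-trips)."""
    path = Path(path)
    serial = 0
    lines: list[str] = []
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            aname = atom.name
            # PDB columns 13-16: element right-justified in 13-14
            pad = f" {aname:<3s}" if len(aname) < 4 else aname
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {pad:<4s} {res.name:<3s} "
                f"{res.chain_id:1s}{res.seq_id:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Gap:
    chain_id: str
    before: ResidueID  # resolved residue preceding the gap
    after: ResidueID   # resolved residue following the gap
    length: int        # missing sequence positions


@dataclass
class GapReport:
    gaps: list[Gap]
    interface_gaps: list[Gap]

    @property
    def n_missing_interface(self) -> int:
        return sum(g.length for g in self.interface_gaps)

    @property
    def excludable(self) -> bool:
        """True when any interface gap is longer than two residues."""
        return any(g.length > 2 for g in self.interface_gaps)


def detect_gaps(
    structure: Structure,
    interface_residues: Iterable[ResidueID] = (),
) -> GapReport:
    """Find discontinuities in author numbering within each tagged chain.

    A gap of length *n* means *n* missing sequence positions between two
    resolved residues; it is an *interface* gap when either flanking
    residue is an interface residue. Residues differing only in insertion
    code are consecutive (no gap). Jumps that look crystallographic
    (negative or > 50) are still reported as gaps and logged for review.
    """
    interface = set(interface_residues)
    gaps: list[Gap] = []
    keep = structure.partner_chains("A") | structure.partner_chains("B")
    for chain_id in structure.chains:
        if chain_id not in keep:
            continue
        chain = structure.chain_residues(chain_id)
        for prev, nxt in zip(chain, chain[1:]):
            delta = nxt.seq_id - prev.seq_id
            if delta <= 1:
                if delta < 0:
                    logger.warning(
                        "chain %s: numbering goes backwards at %s -> %s",
                        chain_id, prev.label(), nxt.label())
                    gaps.append(Gap(chain_id, prev.id, nxt.id,
                                    length=max(1, -delta)))
                continue
            length = delta - 1
            if length > 50:
                logger.warning(
                    "chain %s: numbering jump of %d at %s -> %s "
                    "(possibly crystallographic)", chain_id, delta,
                    prev.label(), nxt.label())
            gaps.append(Gap(chain_id, prev.id, nxt.id, length=length))
    interface_gaps = [
        g for g in gaps if g.before in interface or g.after in interface]
    return GapReport(gaps=gaps, interface_gaps=interface_gaps)
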