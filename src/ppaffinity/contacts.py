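"""Interfacial inter-residue contacts (ICs).

Two residues, one from each partner, are in contact when *any* pair of
their heavy atoms is closer than the distance cutoff (strictly, ``<``).
A residue pair counts once no matter how many atom pairs are within the
cutoff; intra-partner contacts are never counted, including between the
chains of a multi-chain partner. The default cutoff is 5.5 Å, the value
at which the contact count best predicts binding strength on a curated
affinity benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .classification import (
    DEFAULT_TABLES,
    HYDROPATHY_PAIR_CLASSES,
    POLARITY_PAIR_CLASSES,
    ResidueClassTable,
    pair_class,
)
from .structure import Residue, ResidueID, Structure

if TYPE_CHECKING:
    from .surface import SurfaceProfile

__all__ = [
    "ContactSet", "ContactProfile", "ResidueContribution",
    "compute_contacts", "compute_contacts_brute_force", "profile_contacts",
    "residue_contributions", "cutoff_scan", "default_cutoff_grid",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 5.5  # Å


@dataclass
class ContactSet:
    """Interfacial residue pairs at a given cutoff.

    ``pairs`` maps ``(residue_id_A, residue_id_B)`` to the minimal
    heavy-atom distance of the pair (Å).
    """

    cutoff: float
    pairs: dict[tuple[ResidueID, ResidueID], float]

    @property
    def interface_residues_a(self) -> set[ResidueID]:
        return {a for a, _ in self.pairs}

    @property
    def interface_residues_b(self) -> set[ResidueID]:
        return {b for _, b in self.pairs}

    @property
    def interface_residues(self) -> set[ResidueID]:
        return self.interface_residues_a | self.interface_residues_b

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContactProfile:
    """Contact counts, total and per pair-class."""

    ics_total: int
    polarity_counts: dict[str, int]
    hydropathy_counts: dict[str, int]
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        for name in POLARITY_PAIR_CLASSES:
            self.polarity_counts.setdefault(name, 0)
        for name in HYDROPATHY_PAIR_CLASSES:
            self.hydropathy_counts.setdefault(name, 0)
        if (sum(self.polarity_counts.values()) != self.ics_total
                or sum(self.hydropathy_counts.values()) != self.ics_total):
            raise ValueError("pair-class counts do not sum to ics_total")

    def as_properties(self) -> dict[str, float]:
        """Flat mapping using the model property vocabulary (``ICs_*``)."""
        props: dict[str, float] = {"ICs_total": float(self.ics_total)}
        for name, count in self.polarity_counts.items():
            props[f"ICs_{name}"] = float(count)
        for name, count in self.hydropathy_counts.items():
            props[f"ICs_{name}"] = float(count)
        return props


@dataclass
class ResidueContribution:
    residue_id: ResidueID
    residue_name: str
    ic_count: int
    ic_fraction: float  # % of the partner's total contacts
    bsa: float          # Å²
    bsa_fraction: float  # % of the partner's total BSA


def _atom_arrays(residues: Sequence[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coordinates; return (coords, residue index per atom)."""
    coords: list[np.ndarray] = []
    idx: list[int] = []
    for i, res in enumerate(residues):
        c = res.coords
        coords.append(c)
        idx.extend([i] * len(c))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(coords), np.asarray(idx, dtype=int)


def compute_contacts(structure: Structure,
                     cutoff: float = DEFAULT_CUTOFF) -> ContactSet:
    """Enumerate residue pairs with any heavy-atom distance < ``cutoff``.

    Uses a k-d tree over partner B's atoms; equivalent to the brute-force
    all-against-all double loop (checked property in the test suite).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_a = structure.partner_residues("A")
    res_b = structure.partner_residues("B")
    if not res_a or not res_b:
        raise ValueError("both partners must contain residues")

    coords_a, idx_a = _atom_arrays(res_a)
    coords_b, idx_b = _atom_arrays(res_b)
    tree_b = cKDTree(coords_b)
    pairs: dict[tuple[ResidueID, ResidueID], float] = {}
    neighbors = tree_b.query_ball_point(coords_a, r=cutoff)
    for ai, hits in enumerate(neighbors):
        if not hits:
            continue
        d = np.linalg.norm(coords_b[hits] - coords_a[ai], axis=1)
        for bj, dist in zip(hits, d):
            if dist >= cutoff:  # strict inequality at the boundary
                continue
            key = (res_a[idx_a[ai]].id, res_b[idx_b[bj]].id)
            if dist < pairs.get(key, np.inf):
                pairs[key] = float(dist)
    return ContactSet(cutoff=cutoff, pairs=pairs)


def compute_contacts_brute_force(structure: Structure,
                                 cutoff: float = DEFAULT_CUTOFF) -> ContactSet:
    """All-against-all reference implementation (oracle for testing)."""
    res_a = structure.partner_residues("A")
    res_b = structure.partner_residues("B")
    if not res_a or not res_b:
        raise ValueError("both partners must contain residues")
    pairs: dict[tuple[ResidueID, ResidueID], float] = {}
    for ra in res_a:
        ca = ra.coords
        for rb in res_b:
            d = np.linalg.norm(
                ca[:, None, :] - rb.coords[None, :, :], axis=-1).min()
            if d < cutoff:
                pairs[(ra.id, rb.id)] = float(d)
    return ContactSet(cutoff=cutoff, pairs=pairs)


def profile_contacts(
    contact_set: ContactSet,
    structure: Structure,
    tables: ResidueClassTable = DEFAULT_TABLES,
) -> ContactProfile:
    """Decompose a contact set into polarity and hydropathy pair-classes."""
    by_id = {r.id: r for r in structure.residues}
    pol = {name: 0 for name in POLARITY_PAIR_CLASSES}
    hyd = {name: 0 for name in HYDROPATHY_PAIR_CLASSES}
    for (ida, idb) in contact_set.pairs:
        try:
            aa, ab = by_id[ida].one_letter, by_id[idb].one_letter
        except KeyError as exc:
            raise ValueError(
                f"contact residue {exc.args[0]} not found in structure "
                "(contacts and structure must match)") from None
        pol[pair_class(aa, ab, "polarity", tables)] += 1
        hyd[pair_class(aa, ab, "hydropathy", tables)] += 1
    return ContactProfile(
        ics_total=len(contact_set.pairs),
        polarity_counts=pol,
        hydropathy_counts=hyd,
        cutoff=contact_set.cutoff,
    )


def residue_contributions(
    contact_set: ContactSet,
    surface: "SurfaceProfile",
    partner: str,
) -> list[ResidueContribution]:
    """Per-residue share of a partner's contacts and buried surface.

    For each interface residue of the chosen partner, reports the number
    of contacts it participates in and its buried area, each also as a
    percentage of the partner's totals. Percentages within one partner
    sum to 100 (contacts: each pair has exactly one residue on this side;
    BSA: summed over residues with nonzero burial).
    """
    if partner not in ("A", "B"):
        raise ValueError("partner must be 'A' or 'B'")
    pos = 0 if partner == "A" else 1
    counts: dict[ResidueID, int] = {}
    for pair in contact_set.pairs:
        counts[pair[pos]] = counts.get(pair[pos], 0) + 1
    total_ics = sum(counts.values())

    bsa = surface.per_residue_bsa(partner)
    total_bsa = sum(bsa.values())
    names = {r.id: r.name for r in surface.structure.residues}
    missing = set(counts) - set(bsa)
    if missing:
        raise ValueError(
            f"contact residues absent from the surface profile: "
            f"{sorted(missing)[:3]}... — contacts and surface must be "
            "computed on the same structure")

    out = []
    for rid in sorted(set(counts) | {r for r, v in bsa.items() if v > 0}):
        ic = counts.get(rid, 0)
        b = bsa.get(rid, 0.0)
        out.append(ResidueContribution(
            residue_id=rid,
            residue_name=names.get(rid, "UNK"),
            ic_count=ic,
            ic_fraction=100.0 * ic / total_ics if total_ics else 0.0,
            bsa=b,
            bsa_fraction=100.0 * b / total_bsa if total_bsa else 0.0,
        ))
    return out


def default_cutoff_grid() -> list[float]:
    """Distance grid for the cutoff scan: 3–8 Å by 0.5 Å, 8–20 Å by 1.0 Å."""
    fine = np.arange(3.0, 8.0 + 1e-9, 0.5)
    coarse = np.arange(9.0, 20.0 + 1e-9, 1.0)
    return [float(c) for c in np.concatenate([fine, coarse])]


def cutoff_scan(
    structure_set: Sequence[tuple[Structure, float]],
    cutoffs: Sequence[float] | None = None,
):
    """Correlation of total contact counts with experimental ΔG per cutoff.

    Returns a DataFrame with columns ``cutoff, n, r_pearson, s_spearman,
    p_value``; correlations are NaN (undefined) when either variable is
    degenerate.
    """
    import pandas as pd
    from scipy import stats

    if len(structure_set) < 3:
        raise ValueError("cutoff scan needs at least 3 complexes")
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    dgs = np.asarray([dg for _, dg in structure_set], dtype=float)
    rows = []
    for cutoff in cutoffs:
        ics = np.asarray([
            float(len(compute_contacts(s, cutoff))) for s, _ in structure_set])
        if np.ptp(ics) == 0 or np.ptp(dgs) == 0:
            r = s = p = float("nan")
        else:
            r, p = stats.pearsonr(ics, dgs)
            s = stats.spearmanr(ics, dgs).statistic
        rows.append({"cutoff": cutoff, "n": len(dgs), "r_pearson": r,
                     "s_spearman": s, "p_value": p})
    return pd.DataFrame(rows)
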