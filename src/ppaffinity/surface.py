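"""Solvent-accessible surface areas, buried surface area (BSA) and the
composition of the non-interacting surface (NIS).

ASA is computed with the Shrake–Rupley numeric method: each atom carries a
deterministic quasi-uniform point set on a sphere of radius (vdW + probe);
the accessible area is the fraction of points not buried inside any
neighbouring atom's expanded sphere. Radii are NACCESS-compatible and the
probe defaults to 1.4 Å (a water molecule).

BSA follows the difference definition::

    BSA = (ASA_partnerA + ASA_partnerB) - ASA_complex

with the free-partner ASAs computed on the coordinates extracted from the
complex (the separated *bound* conformation — no atoms move).

NIS residues are the solvent-exposed residues of the complex that make no
interfacial contact; the predictor consumes their polar/apolar/charged
percentage composition. "Exposed" means relative ASA in the complex above
a threshold (default 5%, configurable) of the residue type's maximal ASA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._tables import MAX_ASA
from .classification import DEFAULT_TABLES, ResidueClassTable
from .contacts import ContactSet
from .structure import Residue, ResidueID, Structure

__all__ = [
    "SurfaceProfile", "sphere_points", "shrake_rupley", "compute_asa",
    "compute_bsa", "compute_nis", "compute_surface", "relative_accessibility",
    "DEFAULT_PROBE_RADIUS", "DEFAULT_N_POINTS", "DEFAULT_NIS_THRESHOLD",
]

DEFAULT_PROBE_RADIUS = 1.4   # Å, water probe
DEFAULT_N_POINTS = 960       # sphere points per atom
DEFAULT_NIS_THRESHOLD = 5.0  # % relative ASA defining a surface residue


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area, Å².

    Deterministic for a fixed point count: the same input always yields
    the same areas.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    asa = np.empty(len(coords))
    for i in range(len(coords)):
        r_i = expanded[i]
        pts = coords[i] + r_i * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            close = np.linalg.norm(coords[nb] - coords[i], axis=1) \
                < r_i + expanded[nb]
            nb = nb[close]
        else:
            nb = np.empty(0, dtype=int)
        accessible = np.ones(n_points, dtype=bool)
        for j in nb:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= expanded[j] ** 2
        asa[i] = accessible.mean() * 4.0 * math.pi * r_i * r_i
    return asa


def compute_asa(
    residues: Structure | Sequence[Residue],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[ResidueID, float]:
    """Per-residue ASA of a structure (or an explicit residue list), Å².

    When given a :class:`Structure`, only the two tagged partners enter
    the calculation.
    """
    if isinstance(residues, Structure):
        residues = residues.tagged_residues()
    residues = list(residues)
    if not residues or not any(r.atoms for r in residues):
        raise ValueError("no atoms to compute ASA for")
    coords = np.vstack([r.coords for r in residues])
    radii = np.concatenate([r.radii for r in residues])
    per_atom = shrake_rupley(coords, radii, probe_radius, n_points)
    out: dict[ResidueID, float] = {}
    start = 0
    for r in residues:
        stop = start + len(r.atoms)
        out[r.id] = float(per_atom[start:stop].sum())
        start = stop
    return out


@dataclass
class SurfaceProfile:
    """Accessible-area bookkeeping for one complex."""

    structure: Structure
    asa_complex: dict[ResidueID, float]
    asa_free_a: dict[ResidueID, float]
    asa_free_b: dict[ResidueID, float]
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_points: int = DEFAULT_N_POINTS
    # NIS composition, filled by compute_nis
    nis_polar: float | None = None
    nis_apolar: float | None = None
    nis_charged: float | None = None
    nis_residues: set[ResidueID] = field(default_factory=set)
    nis_threshold: float = DEFAULT_NIS_THRESHOLD

    def per_residue_bsa(self, partner: str) -> dict[ResidueID, float]:
        """Buried area per residue of one partner (free − complex), Å²."""
        free = self.asa_free_a if partner == "A" else self.asa_free_b
        return {rid: max(0.0, a - self.asa_complex.get(rid, 0.0))
                for rid, a in free.items()}

    @property
    def bsa_total(self) -> float:
        asa_free = (sum(self.asa_free_a.values())
                    + sum(self.asa_free_b.values()))
        return max(0.0, asa_free - sum(self.asa_complex.values()))

    def _bsa_by_polarity(self, tables: ResidueClassTable = DEFAULT_TABLES
                         ) -> dict[str, float]:
        by_id = {r.id: r for r in self.structure.residues}
        split = {"polar": 0.0, "apolar": 0.0, "charged": 0.0}
        for partner in ("A", "B"):
            for rid, b in self.per_residue_bsa(partner).items():
                split[tables.polarity_class[by_id[rid].one_letter]] += b
        return split

    @property
    def bsa_polar(self) -> float:
        """Polar-side BSA; charged residues are grouped with polar."""
        split = self._bsa_by_polarity()
        return split["polar"] + split["charged"]

    @property
    def bsa_apolar(self) -> float:
        return self._bsa_by_polarity()["apolar"]

    def as_properties(self) -> dict[str, float]:
        """Flat mapping using the model property vocabulary."""
        props = {
            "BSA_total": self.bsa_total,
            "BSA_polar": self.bsa_polar,
            "BSA_apolar": self.bsa_apolar,
        }
        if self.nis_polar is not None:
            props["%NIS_polar"] = self.nis_polar
            props["%NIS_apolar"] = self.nis_apolar
            props["%NIS_charged"] = self.nis_charged
        return props


def relative_accessibility(
    structure: Structure,
    asa: dict[ResidueID, float],
) -> dict[ResidueID, float]:
    """Per-residue ASA as % of the residue type's maximal (Ala-X-Ala) ASA."""
    out = {}
    for res in structure.tagged_residues():
        if res.id in asa:
            out[res.id] = 100.0 * asa[res.id] / MAX_ASA[res.one_letter]
    return out


def compute_bsa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SurfaceProfile:
    """ASA of the complex and of each separated partner; BSA by difference.

    Partner coordinates are taken from the complex unchanged (bound
    conformation), so BSA is exactly the area occluded by association.
    """
    res_a = structure.partner_residues("A")
    res_b = structure.partner_residues("B")
    asa_complex = compute_asa(res_a + res_b, probe_radius, n_points)
    asa_free_a = compute_asa(res_a, probe_radius, n_points)
    asa_free_b = compute_asa(res_b, probe_radius, n_points)
    return SurfaceProfile(
        structure=structure,
        asa_complex=asa_complex,
        asa_free_a=asa_free_a,
        asa_free_b=asa_free_b,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def compute_nis(
    structure: Structure,
    contact_set: ContactSet,
    rel_asa_threshold: float = DEFAULT_NIS_THRESHOLD,
    surface: SurfaceProfile | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    tables: ResidueClassTable = DEFAULT_TABLES,
) -> SurfaceProfile:
    """Polar/apolar/charged composition of the non-interacting surface.

    NIS residues are those whose relative ASA *in the complex* exceeds
    ``rel_asa_threshold`` and that appear in no interfacial contact.
    Percentages are residue-count fractions per polarity class and sum
    to 100.
    """
    if surface is None:
        surface = compute_bsa(structure, probe_radius, n_points)
    rel = relative_accessibility(structure, surface.asa_complex)
    interface = contact_set.interface_residues
    by_id = {r.id: r for r in structure.residues}
    nis = {rid for rid, r in rel.items()
           if r > rel_asa_threshold and rid not in interface}
    if not nis:
        raise ValueError(
            "no non-interacting surface residues found (degenerate "
            "structure or threshold too high)")
    counts = {"polar": 0, "apolar": 0, "charged": 0}
    for rid in nis:
        counts[tables.polarity_class[by_id[rid].one_letter]] += 1
    n = len(nis)
    surface.nis_polar = 100.0 * counts["polar"] / n
    surface.nis_apolar = 100.0 * counts["apolar"] / n
    surface.nis_charged = 100.0 * counts["charged"] / n
    surface.nis_residues = nis
    surface.nis_threshold = rel_asa_threshold
    return surface


def compute_surface(
    structure: Structure,
    contact_set: ContactSet,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    nis_threshold: float = DEFAULT_NIS_THRESHOLD,
) -> SurfaceProfile:
    """BSA and NIS in one pass (the full surface profile of a complex)."""
    profile = compute_bsa(structure, probe_radius, n_points)
    return compute_nis(structure, contact_set, nis_threshold,
                       surface=profile)
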