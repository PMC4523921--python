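"""Residue physico-chemical classification and contact pair-classes.

Residues fall into three polarity classes::

    polar   : C, H, N, Q, S, T, Y, W
    apolar  : A, F, G, I, V, M, P
    charged : E, D, K, R

and two hydropathy classes derived from the Kyte–Doolittle index
(hydrophobic iff index > 0, the standard sign convention).

A contact between a residue of partner A and one of partner B is labelled
by the pair of classes. Polarity pair-classes are *unordered*
(charged/apolar ≡ apolar/charged, canonicalised charged < polar < apolar);
hydropathy pair-classes are *ordered*, A-side class first, because the
affinity model treats hydrophilic/hydrophobic and hydrophobic/hydrophilic
as distinct predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._tables import KD_INDEX, ONE_TO_THREE, POLARITY_CLASS

__all__ = [
    "ResidueClassTable",
    "DEFAULT_TABLES",
    "polarity_of",
    "hydropathy_of",
    "pair_class",
    "POLARITY_PAIR_CLASSES",
    "HYDROPATHY_PAIR_CLASSES",
]

_POLARITY_RANK = {"charged": 0, "polar": 1, "apolar": 2}

#: Canonical order of the six unordered polarity pair-classes.
POLARITY_PAIR_CLASSES: tuple[str, ...] = (
    "charged/charged", "charged/polar", "charged/apolar",
    "polar/polar", "polar/apolar", "apolar/apolar",
)

#: The four ordered hydropathy pair-classes (A-side first).
HYDROPATHY_PAIR_CLASSES: tuple[str, ...] = (
    "hydrophilic/hydrophilic", "hydrophilic/hydrophobic",
    "hydrophobic/hydrophilic", "hydrophobic/hydrophobic",
)


def _default_hydropathy() -> dict[str, str]:
    return {
        aa: ("hydrophobic" if kd > 0 else "hydrophilic")
        for aa, kd in KD_INDEX.items()
    }


@dataclass(frozen=True)
class ResidueClassTable:
    """Lookup tables mapping 1-letter codes to classes.

    The defaults reproduce the published partition; alternate tables can be
    supplied for sensitivity analyses but must cover all 20 amino acids.
    """

    polarity_class: dict[str, str] = field(
        default_factory=lambda: dict(POLARITY_CLASS))
    hydropathy_class: dict[str, str] = field(
        default_factory=_default_hydropathy)
    kd_index: dict[str, float] = field(default_factory=lambda: dict(KD_INDEX))

    def __post_init__(self) -> None:
        covered = set(self.polarity_class)
        if covered != set(ONE_TO_THREE):
            raise ValueError(
                "polarity table must cover exactly the 20 standard amino "
                f"acids; got {sorted(covered)}")

    def to_text(self) -> str:
        """Plain-text rendering of the class tables (for documentation)."""
        lines = ["aa\tpolarity\thydropathy\tkd_index"]
        for aa in sorted(ONE_TO_THREE):
            lines.append(
                f"{aa}\t{self.polarity_class[aa]}\t"
                f"{self.hydropathy_class[aa]}\t{self.kd_index[aa]:+.1f}")
        return "\n".join(lines) + "\n"


DEFAULT_TABLES = ResidueClassTable()


def _check_code(code: str, table: dict[str, str]) -> str:
    code = code.upper()
    if code not in table:
        raise KeyError(f"unknown amino-acid code {code!r}")
    return code


def polarity_of(code: str, tables: ResidueClassTable = DEFAULT_TABLES) -> str:
    """Polarity class (``polar``/``apolar``/``charged``) of a 1-letter code."""
    return tables.polarity_class[_check_code(code, tables.polarity_class)]


def hydropathy_of(code: str, tables: ResidueClassTable = DEFAULT_TABLES) -> str:
    """Hydropathy class: ``hydrophobic`` iff Kyte–Doolittle index > 0."""
    return tables.hydropathy_class[_check_code(code, tables.hydropathy_class)]


def pair_class(
    code_a: str,
    code_b: str,
    scheme: str = "polarity",
    tables: ResidueClassTable = DEFAULT_TABLES,
) -> str:
    """Pair-class label for a contact between an A-side and a B-side residue.

    Parameters
    ----------
    code_a, code_b
        1-letter codes; ``code_a`` belongs to partner A.
    scheme
        ``"polarity"`` (unordered, 6 classes) or ``"hydropathy"``
        (ordered A-side first, 4 classes).
    """
    if scheme == "polarity":
        ca, cb = polarity_of(code_a, tables), polarity_of(code_b, tables)
        ca, cb = sorted((ca, cb), key=_POLARITY_RANK.__getitem__)
        return f"{ca}/{cb}"
    if scheme == "hydropathy":
        return f"{hydropathy_of(code_a, tables)}/{hydropathy_of(code_b, tables)}"
    raise ValueError(f"unknown scheme {scheme!r}")
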