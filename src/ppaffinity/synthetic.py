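"""Synthetic fixtures with known ground truth.

Two generators make the whole pipeline testable without any downloads:

* :func:`make_toy_complex` builds a small artificial two-chain structure
  whose interfacial contacts are known by construction — pseudo-residues
  (one CA atom each) on a lattice, with requested contact pairs placed at
  a controlled distance and everything else kept far apart. Residues
  carry real amino-acid names so classification is exercised; the
  geometry is lattice-based, not biochemical.

* :func:`make_regression_dataset` draws tabular property records from a
  known linear ΔG model plus Gaussian noise. Defaults reproduce the
  published final predictor's weights (the ICs/NIS model) with σ = 1
  kcal/mol and property magnitudes spanning the range of a real affinity
  benchmark, so fits against it probe coefficient recovery under
  realistic signal-to-noise.

All randomness flows through explicit seeds; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import pair_class
from .contacts import (
    DEFAULT_CUTOFF,
    HYDROPATHY_PAIR_CLASSES,
    POLARITY_PAIR_CLASSES,
    ContactProfile,
)
from .models import BUILTIN_MODELS
from .structure import Atom, Residue, Structure
from ._tables import ONE_TO_THREE

__all__ = [
    "ToyComplexSpec", "SyntheticDatasetSpec", "make_toy_complex",
    "random_toy_complex", "make_regression_dataset", "write_dataset_tsv",
]

#: Representative residues per class used when a pair is requested by
#: class label rather than by explicit amino acids.
_CLASS_REPRESENTATIVE = {
    "charged": "K", "polar": "S", "apolar": "L",
    "hydrophilic": "S", "hydrophobic": "I",
}

_MIN_INTRA_DIST = 1.5  # Å, hard floor for atoms within one partner


@dataclass
class ToyComplexSpec:
    """Recipe for an artificial two-chain complex.

    ``contact_pairs`` lists the intended interfacial contacts, each as a
    pair of 1-letter amino-acid codes (A-side, B-side) or a pair-class
    label like ``"charged/apolar"``. Extra residues per partner are
    placed far from the interface and never make contacts.
    """

    contact_pairs: Sequence[tuple[str, str] | str] = ()
    n_extra_a: int = 0
    n_extra_b: int = 0
    spacing: float = 8.0           # Å between lattice neighbours
    contact_distance: float = 4.0  # Å between intended contact partners
    partner_separation: float = 50.0  # Å, used when no contacts requested
    extra_offset: float = 30.0     # Å, distance of extras from the interface
    seed: int = 0

    def resolved_pairs(self) -> list[tuple[str, str]]:
        out = []
        for p in self.contact_pairs:
            if isinstance(p, str):
                ca, cb = p.split("/")
                out.append((_CLASS_REPRESENTATIVE[ca],
                            _CLASS_REPRESENTATIVE[cb]))
            else:
                out.append((p[0].upper(), p[1].upper()))
        return out


def _residue(chain: str, seq: int, one_letter: str, xyz) -> Residue:
    return Residue(
        chain_id=chain, seq_id=seq, icode="",
        name=ONE_TO_THREE[one_letter],
        atoms=[Atom(name="CA", element="C",
                    coord=np.asarray(xyz, dtype=float))])


def make_toy_complex(
    spec: ToyComplexSpec,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[Structure, ContactProfile]:
    """Build the structure and its ground-truth contact profile.

    Exactly the requested pairs fall under ``cutoff``; the profile is
    derived from the requested amino acids, independently of the contact
    detector.
    """
    pairs = spec.resolved_pairs()
    if spec.spacing < _MIN_INTRA_DIST:
        raise ValueError("spacing below the 1.5 Å intra-partner floor")
    if pairs:
        if not (_MIN_INTRA_DIST <= spec.contact_distance < cutoff):
            raise ValueError(
                f"contact distance {spec.contact_distance} not in "
                f"[{_MIN_INTRA_DIST}, cutoff {cutoff})")
        if np.hypot(spec.spacing, spec.contact_distance) <= cutoff:
            raise ValueError("spacing too small: unintended cross contacts")
        if spec.extra_offset <= cutoff + spec.contact_distance:
            raise ValueError("extra_offset too small to isolate extras")

    rng = np.random.default_rng(spec.seed)
    sep = spec.contact_distance if pairs else spec.partner_separation
    res_a: list[Residue] = []
    res_b: list[Residue] = []
    for i, (aa, ab) in enumerate(pairs):
        x = i * spec.spacing
        res_a.append(_residue("A", i + 1, aa, (x, 0.0, 0.0)))
        res_b.append(_residue("B", i + 1, ab, (x, sep, 0.0)))
    letters = list(_CLASS_REPRESENTATIVE.values())
    for j in range(spec.n_extra_a):
        res_a.append(_residue(
            "A", len(pairs) + j + 1, rng.choice(letters),
            (j * spec.spacing, -spec.extra_offset, 0.0)))
    for j in range(spec.n_extra_b):
        res_b.append(_residue(
            "B", len(pairs) + j + 1, rng.choice(letters),
            (j * spec.spacing, sep + spec.extra_offset, 0.0)))
    if not res_a or not res_b:
        # partners must be non-empty even for a contact-free complex
        if not res_a:
            res_a.append(_residue("A", 1, "G", (0.0, 0.0, 0.0)))
        if not res_b:
            res_b.append(_residue("B", 1, "G", (0.0, sep, 0.0)))

    structure = Structure(
        residues=res_a + res_b,
        partner_of={"A": "A", "B": "B"},
        name=f"toy-{spec.seed}")

    pol = {name: 0 for name in POLARITY_PAIR_CLASSES}
    hyd = {name: 0 for name in HYDROPATHY_PAIR_CLASSES}
    for aa, ab in pairs:
        pol[pair_class(aa, ab, "polarity")] += 1
        hyd[pair_class(aa, ab, "hydropathy")] += 1
    profile = ContactProfile(
        ics_total=len(pairs), polarity_counts=pol,
        hydropathy_counts=hyd, cutoff=cutoff)
    return structure, profile


def random_toy_complex(seed: int, max_residues_per_side: int = 50) -> Structure:
    """A random jittered-lattice complex for oracle-equivalence testing.

    Atoms within a partner sit on distinct 2.2 Å lattice cells with ±0.2 Å
    jitter (intra-partner distances stay above the 1.5 Å floor); partner B
    is shifted so the slabs interpenetrate enough to form contacts.
    """
    rng = np.random.default_rng(seed)
    aa_codes = list(ONE_TO_THREE)

    def one_partner(chain: str, n: int, offset: np.ndarray) -> list[Residue]:
        side = int(np.ceil(n ** (1 / 3))) + 1
        cells = rng.choice(side ** 3, size=n, replace=False)
        coords = np.column_stack(np.unravel_index(cells, (side,) * 3))
        coords = coords * 2.2 + rng.uniform(-0.2, 0.2, coords.shape) + offset
        return [_residue(chain, i + 1, rng.choice(aa_codes), coords[i])
                for i in range(n)]

    n_a = int(rng.integers(3, max_residues_per_side + 1))
    n_b = int(rng.integers(3, max_residues_per_side + 1))
    shift = np.array([rng.uniform(2.0, 8.0), 0.0, 0.0])
    res_a = one_partner("A", n_a, np.zeros(3))
    extent = max(r.atoms[0].coord[0] for r in res_a)
    res_b = one_partner("B", n_b, shift + np.array([extent, 0.0, 0.0]))
    return Structure(residues=res_a + res_b,
                     partner_of={"A": "A", "B": "B"},
                     name=f"rand-{seed}")


def _default_weights() -> dict[str, float]:
    return dict(BUILTIN_MODELS["model6"].terms_)


def _default_ranges() -> dict[str, tuple[float, float]]:
    # magnitudes matching a real benchmark: tens of contacts per class,
    # BSA in the 800-3400 Å² range, NIS percentages summing to 100
    return {
        "ICs_charged/charged": (0, 12),
        "ICs_charged/polar": (0, 15),
        "ICs_charged/apolar": (0, 18),
        "ICs_polar/polar": (0, 15),
        "ICs_polar/apolar": (0, 25),
        "ICs_apolar/apolar": (0, 20),
        "%NIS_apolar": (25, 45),
        "%NIS_charged": (15, 35),
        "BSA_total": (800, 3400),
    }


@dataclass
class SyntheticDatasetSpec:
    """Recipe for a tabular dataset with a known linear ΔG model."""

    n: int = 81
    weights: dict[str, float] = field(default_factory=_default_weights)
    intercept: float = 15.9433
    noise_sigma: float = 1.0  # kcal/mol
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_ranges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


_METHOD_CYCLE = ("SPR", "ITC", "stopped-flow", "spectroscopy",
                 "inhibition assay", "fluorescence")
_CLASS_CYCLE = ("EI", "A", "ES", "ER", "OG", "OR", "OX", "NC")


def make_regression_dataset(spec: SyntheticDatasetSpec) -> pd.DataFrame:
    """Draw records from ΔG = Σ w·P + Q + N(0, σ); seeded, reproducible.

    Contact counts are integers; ``ICs_total`` is the sum of the six
    polarity pair-classes and the hydropathy counts are a multinomial
    split of it, so the count-consistency invariants of real contact
    profiles hold. ``%NIS_polar`` closes the NIS composition to 100%.
    ``dg_exp`` is negative (the experimental sign convention).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    for name, (lo, hi) in spec.ranges.items():
        if name.startswith("ICs_"):
            cols[name] = rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
        else:
            cols[name] = rng.uniform(lo, hi, size=n)
    pol_cols = [f"ICs_{c}" for c in POLARITY_PAIR_CLASSES]
    cols["ICs_total"] = np.sum([cols[c] for c in pol_cols], axis=0)
    hyd = np.array([rng.multinomial(int(t), [0.35, 0.25, 0.25, 0.15])
                    for t in cols["ICs_total"]], dtype=float)
    for i, c in enumerate(HYDROPATHY_PAIR_CLASSES):
        cols[f"ICs_{c}"] = hyd[:, i]
    cols["%NIS_polar"] = 100.0 - cols["%NIS_apolar"] - cols["%NIS_charged"]
    frac = rng.uniform(0.40, 0.60, size=n)
    cols["BSA_polar"] = frac * cols["BSA_total"]
    cols["BSA_apolar"] = cols["BSA_total"] - cols["BSA_polar"]

    dg_abs = np.full(n, spec.intercept, dtype=float)
    for name, w in spec.weights.items():
        if name not in cols:
            raise KeyError(f"no range generates weighted property {name!r}")
        dg_abs = dg_abs + w * cols[name]
    dg_abs = dg_abs + rng.normal(0.0, spec.noise_sigma, size=n)

    df = pd.DataFrame({
        "id": [f"synth{i:04d}" for i in range(n)],
        "dg_exp": -dg_abs,
        "method": [_METHOD_CYCLE[i % len(_METHOD_CYCLE)] for i in range(n)],
        "i_rmsd": rng.uniform(0.17, 4.9, size=n),
        "class": [_CLASS_CYCLE[i % len(_CLASS_CYCLE)] for i in range(n)],
    })
    for name in sorted(cols):
        df[name] = cols[name]
    return df


def write_dataset_tsv(df: pd.DataFrame, path) -> None:
    """Write a dataset in the TSV schema the training module reads."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
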