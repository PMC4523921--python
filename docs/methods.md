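# Methods

## The model

`ppaffinity` predicts the binding affinity of a protein–protein complex
from its bound 3D structure. Affinity is expressed either as the Gibbs
free energy of dissociation, ΔG (kcal·mol⁻¹, negative = favourable), or
the dissociation constant K_d via ΔG = RT ln K_d with
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 298.15 K.

Every predictor is linear in structural properties of the complex,

    ΔG_calc = Σ_N w_N · P_N + Q ,

where the properties P_N are:

* **ICs** — inter-residue contacts across the interface. Two residues,
  one from each partner, are in contact when any pair of their heavy
  atoms lies strictly closer than the cutoff (default 5.5 Å). A residue
  pair counts once regardless of how many atom pairs qualify. Contacts
  are subdivided by the polarity classes of the contacting residues
  (polar: C H N Q S T Y W; apolar: A F G I L V M P; charged: E D K R) into
  six unordered pair-classes, and by Kyte–Doolittle hydropathy
  (hydrophobic ⇔ index > 0) into four ordered pair-classes.
* **BSA** — buried surface area,
  BSA = (ASA_partner1 + ASA_partner2) − ASA_complex, with partner ASAs
  computed on coordinates extracted from the complex (separated *bound*
  conformations; no atoms move).
* **%NIS** — the polar/apolar/charged residue-count composition of the
  non-interacting surface: solvent-exposed residues of the complex
  (relative ASA above a threshold, default 5%) that make no interfacial
  contact.

Six fixed models ship with the published weights; the final predictor
(model 6) combines four polarity contact classes with the apolar and
charged NIS percentages:

    |ΔG| = 0.09459·ICs_charged/charged + 0.10007·ICs_charged/apolar
         − 0.19577·ICs_polar/polar    + 0.22671·ICs_polar/apolar
         − 0.18681·%NIS_apolar        − 0.13810·%NIS_charged + 15.9433

The fixed models produce the *magnitude* of the free energy; the
physical ΔG is its negation. This matches the convention of training
against absolute experimental affinities, and is why the regression
target throughout the training module is |ΔG|.

Leucine is absent from the published polarity lists; it is assigned
apolar here (aliphatic side chain, Kyte–Doolittle +3.8) — the only
assignment consistent with standard practice.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| contact cutoff | 5.5 | Å | re-optimised contact definition on the curated benchmark; scan grid 3–8 Å by 0.5 and 8–20 Å by 1.0 |
| probe radius | 1.4 | Å | water-sized probe, the standard choice |
| sphere points / atom | 960 | — | Shrake–Rupley quadrature; doubling changes totals by <1% on fixtures |
| NIS relative-ASA threshold | 5 | % | defines "surface" residues; exposed as a config knob because the literature varies |
| temperature | 298.15 | K | K_d conversion only; configurable |

Atomic radii are NACCESS-compatible (N 1.65, O 1.40, S 1.85, sp³ C
1.87, sp²/aromatic/carbonyl C 1.76 Å). Relative accessibility uses
Ala-X-Ala theoretical maximal areas. The reference ASA method used when
the published models were derived was Lee–Richards; Shrake–Rupley
agrees within a few percent, which is why surface-area comparisons in
the tests carry ~1–2% tolerances rather than exact equality.

## Structure handling

PDB files are read through Bio.PDB. Cleanup is fixed for
reproducibility: hydrogens, waters and hetero-residues are discarded;
modified residues with a standard parent (MSE→MET, SEP→SER, …) are
mapped, others skipped with a warning; for alternate locations the
highest-occupancy conformer wins, ties broken alphabetically by altloc
code. Residues keep author numbering — the identity key is
(chain, number, insertion code) throughout.

Gap detection flags discontinuities in author numbering within each
partner chain; a structure is marked excludable when a gap longer than
two residues touches the interface (either flanking residue is an
interface residue). Insertion-coded residues count as consecutive
positions; suspicious jumps (negative, or longer than 50) are still
reported as gaps but logged for curator review rather than silently
interpreted.

## Training machinery

Fits are ordinary least squares (statsmodels) of |ΔG| on named property
columns. Stepwise term selection minimises the Gaussian-likelihood AIC,
n·ln(RSS/n) + 2(k+1), with greedy add/drop moves accepted while the AIC
decreases; drops are considered before adds and terms in declared
order, making the procedure deterministic. Note that AIC is not a
consistent selector: a term whose true weight is zero survives with
probability P(χ²₁ > 2) ≈ 0.16 independent of sample size, so with
several null candidates the *exact* recovery of a sparse true model
happens in only about half of replicates even at high signal-to-noise —
the relevant guarantee, which the test suite checks, is that strong true
terms are always retained and selection never increases the AIC.

Cross-validation is repeated k-fold (default 4 folds × 10 repeats),
unstratified, with a mandatory seed; every record is held out exactly
once per repeat. Grouped evaluation splits by experimental-method label
or by conformational rigidity (interface RMSD ≤ 1.0 Å = rigid).
Benchmark curation drops entries whose affinity is an inequality rather
than a number and entries with interface gaps, and can restrict to the
reliable direct methods (stopped-flow, SPR, spectroscopy, ITC).

## Synthetic fixtures: what they do and do not show

The toy-complex generator places single-atom pseudo-residues on a
lattice so that exactly the requested contact pairs fall inside the
cutoff; residues carry real amino-acid names, so classification,
surface bookkeeping and the full prediction pipeline are exercised with
known ground truth. The tabular generator draws property vectors
uniformly (contact counts as integers, NIS percentages closing to
100%, BSA splits consistent) and produces ΔG from a known linear model
plus Gaussian noise — by default the published six-term weights with
σ = 1 kcal·mol⁻¹ at benchmark-like property magnitudes and n = 81.

These fixtures validate geometry, accounting and statistics. They do
not emulate real protein shape: no side chains, no packing, no
correlation structure between contact classes and surface composition,
and no experimental-method heterogeneity beyond labels. Passing tests
therefore demonstrate that the machinery is correct, not that the
published accuracy transfers to new complexes; reproducing
benchmark-wide correlations requires the real structures
(`scripts/benchmark_correlations.py`, network required).

## Numerical choices

* Contact boundary: strictly `<` cutoff. Boundary ties are measure-zero
  on real coordinates; a fixed convention guarantees reproducibility.
* Shrake–Rupley points come from a deterministic golden-spiral
  construction — identical input always gives identical areas.
* BSA polar/apolar split: the published tables carry only polar and
  apolar columns, so charged residues fold into the polar side
  (standard hydrophilic grouping).
* Hydropathy pair-classes are ordered with the first-named partner
  first, because hydrophilic/hydrophobic and hydrophobic/hydrophilic
  carry different published weights; which molecule is "first" is the
  caller's choice of partner A. All four ordered classes are computed,
  including hydrophobic/hydrophobic.
* Degenerate correlation inputs (zero variance) raise or report NaN —
  never a silent 0.
* Problem sizes in the acceptance script (100 oracle structures of ≤50
  residues/side, 100 regression replicates at n = 200, 4×10 CV on
  n = 200) are chosen so the whole run completes in seconds while
  keeping Monte-Carlo rates stable to a few percent.

## Known limitations

* Single-model NMR/X-ray structures only; no ensemble averaging.
* No structure repair or protonation; entries with unresolved interface
  segments should be excluded via the gap report, as in the original
  curation.
* The NIS definition (threshold, complex-form ASA) follows a documented
  default; the originating literature leaves room for variation, so the
  threshold is a configuration knob.
* Fixed-weight models are only as transferable as their training set —
  affinities measured by indirect methods (inhibition, fluorescence
  competition) correlate poorly with structure-derived predictors.
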