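# ppaffinity

Contacts-based binding-affinity prediction for protein–protein
complexes.

Experimental dissociation constants are slow and expensive to measure,
yet the binding affinity (ΔG = RT ln K_d) is what decides whether two
proteins associate. Given the bound 3D structure of a complex and the
chain composition of its two interactors, `ppaffinity` predicts ΔG and
K_d from remarkably simple structural descriptors: the network of
interfacial residue–residue contacts, classified by the
physico-chemical character of the contacting residues, combined with
the composition of the non-interacting surface. It is aimed at
structural biologists and modellers who need fast affinity estimates
for crystal structures, docking models or designed interfaces.

## The model

Two residues from opposite partners are *in contact* (an IC) when any
pair of their heavy atoms is closer than 5.5 Å. Contacts are split by
the residue polarity classes (polar / apolar / charged), the buried
surface area BSA = (ASA₁ + ASA₂) − ASA_complex is measured with a
1.4 Å probe, and %NIS_x is the percentage of class-x residues on the
solvent-exposed, non-interacting surface. All predictors are linear,
ΔG_calc = Σ w_N·P_N + Q; the flagship six-term model is

```
|ΔG| = 0.09459·ICs_charged/charged + 0.10007·ICs_charged/apolar
     − 0.19577·ICs_polar/polar    + 0.22671·ICs_polar/apolar
     − 0.18681·%NIS_apolar        − 0.13810·%NIS_charged + 15.9433
```

in kcal·mol⁻¹ (the physical ΔG is the negation). Five simpler
published variants (total ICs, total BSA, polarity- or
hydropathy-classified ICs, polar/apolar BSA) are also built in, along
with the full training stack used to derive such models: OLS fitting of
|ΔG|, AIC stepwise term selection, Pearson/Spearman/RMSE evaluation,
grouped evaluation by experimental method or conformational rigidity,
and repeated 4-fold cross-validation.

## Worked example

Generate a synthetic two-chain complex with known contacts and predict
its affinity:

```
$ ppaffinity fixtures demo --seed 7
$ ppaffinity predict --partners A:B --model model6 demo/toy_complex.pdb
{
  "model": "model6",
  "dg_kcal_mol": -6.511470000000001,
  "dg_abs_kcal_mol": 6.511470000000001,
  "kd_M": 1.6848790181950944e-05,
  "temperature_K": 298.15,
  "properties": {
    "ICs_charged/charged": 0.0,
    "ICs_charged/apolar": 3.0,
    "ICs_polar/polar": 2.0,
    "ICs_polar/apolar": 0.0,
    "%NIS_apolar": 50.0,
    "%NIS_charged": 0.0
  }
}
```

The fixture places 3 charged/apolar and 2 polar/polar contact pairs at
the interface; half of its non-interacting residues are apolar. Feeding
those properties through the six-term model gives |ΔG| = 6.51
kcal·mol⁻¹, i.e. ΔG = −6.51 kcal·mol⁻¹ and K_d ≈ 17 µM at 298.15 K — a
weak binder, as expected for an interface of only five contacts.

The same pipeline is available as a library, sklearn-style:

```python
from ppaffinity import InterfaceFeaturizer, builtin_model, load_structure

structure = load_structure("complex.pdb", partner_a={"H", "L"}, partner_b={"T"})
X = InterfaceFeaturizer(cutoff=5.5).fit_transform([structure])
dg = builtin_model("model6").predict_dg(X)   # kcal/mol, negative
```

Other subcommands: `contacts` (interface pair table), `surface`
(per-residue ASA/BSA and NIS composition), `scan` (contact–affinity
correlation over a cutoff grid), `train` / `crossval` (model fitting on
a dataset TSV), `fixtures` (synthetic test data).

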