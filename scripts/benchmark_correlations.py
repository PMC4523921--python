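"""Reproduce benchmark-wide correlations on a downloaded affinity benchmark.

This is an optional, network-dependent companion script: it expects a
local directory of PDB files and a manifest TSV describing the benchmark
(neither ships with the package). For every entry it runs the full
structural pipeline, evaluates the final ICs/NIS model, and reports
Pearson/Spearman correlations and RMSE against the experimental ΔG,
overall and per experimental-method / rigidity group.

Manifest columns (TSV): id, pdb_path (relative to --pdb-dir), partners
(e.g. "H,L:T"), dg_exp (kcal/mol, negative), method, i_rmsd.

Usage::

    python scripts/benchmark_correlations.py manifest.tsv --pdb-dir pdbs/
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ppaffinity.features import compute_properties
from ppaffinity.models import builtin_model
from ppaffinity.structure import load_structure, parse_partner_spec
from ppaffinity.training import correlations, curate, grouped_eval


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("manifest", type=Path)
    parser.add_argument("--pdb-dir", type=Path, default=Path("."))
    parser.add_argument("--model", default="model6")
    parser.add_argument("--cutoff", type=float, default=5.5)
    parser.add_argument("--reliable-only", action="store_true",
                        help="Keep stopped-flow/SPR/spectroscopy/ITC only.")
    args = parser.parse_args()

    table = pd.read_csv(args.manifest, sep="\t")
    model = builtin_model(args.model)
    rows = []
    for _, entry in table.iterrows():
        a, b = parse_partner_spec(entry["partners"])
        structure = load_structure(args.pdb_dir / entry["pdb_path"], a, b)
        props = compute_properties(structure, cutoff=args.cutoff)
        rows.append({**entry, **props,
                     "dg_pred": -model.evaluate(props)})
    df = pd.DataFrame(rows)
    df = curate(df, reliable_only=args.reliable_only)

    y = np.abs(df["dg_exp"].to_numpy(dtype=float))
    pred = np.abs(df["dg_pred"].to_numpy())
    r, s, p = correlations(pred, y)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    print(f"n={len(df)}  R={r:.3f}  S={s:.3f}  RMSE={rmse:.2f} kcal/mol  "
          f"(p={p:.2g})")
    for key in ("method", "rigidity"):
        try:
            print(f"\nby {key}:")
            print(grouped_eval(df, key, value_col="dg_pred")
                  .to_string(index=False))
        except KeyError:
            pass


if __name__ == "__main__":
    main()
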