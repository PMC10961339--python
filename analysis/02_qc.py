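#!/usr/bin/env python
"""QC-filter and log-normalize every study bundle (run after 01_simulate.py).

Applies the standard filters — genes detected in <=5 cells removed, cells
outside the 2nd..98th percentile of expressed-gene counts removed — then
counts-per-10K log normalization, per study. Writes normalized bundles to
scratch/qc/ and a retention summary to results/.
"""

from pathlib import Path

import pandas as pd

from mpkit.io import read_bundle, write_bundle
from mpkit.qc import QCConfig, run_qc

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    data_dir = ROOT / "scratch" / "data"
    if not data_dir.exists():
        raise SystemExit("no scratch/data — run analysis/01_simulate.py first")
    qc_dir = ROOT / "scratch" / "qc"
    rows = []
    for bundle in sorted(p for p in data_dir.iterdir()
                         if p.is_dir() and p.name != "truth"):
        m = read_bundle(bundle)
        norm = run_qc(m, QCConfig())
        write_bundle(norm, qc_dir / bundle.name)
        rows.append({"study": bundle.name,
                     "genes_in": m.n_genes, "genes_kept": norm.n_genes,
                     "cells_in": m.n_cells, "cells_kept": norm.n_cells})
    out = ROOT / "results" / "02_qc_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"normalized bundles -> {qc_dir}; summary -> {out}")


if __name__ == "__main__":
    main()
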