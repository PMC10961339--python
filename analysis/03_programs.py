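#!/usr/bin/env python
"""Extract NMF gene programs per study and select the robust set per entity
(run after 02_qc.py).

Each study is factorized at ranks k = 4..9 (39 programs per study, top 50
genes per factor); a program is kept as robust when it is reproduced at a
different rank within its study (>=35/50 shared genes) and echoed by a
program in another study of the same entity (>20% shared genes). Writes
per-entity program JSON to scratch/ and a count table to results/.
"""

import warnings
from collections import defaultdict
from pathlib import Path

import pandas as pd

from mpkit.cli import write_programs_json
from mpkit.io import read_bundle
from mpkit.nmf import NMFConfig, run_nmf_grid, select_robust

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    qc_dir = ROOT / "scratch" / "qc"
    if not qc_dir.exists():
        raise SystemExit("no scratch/qc — run analysis/02_qc.py first")
    cfg = NMFConfig()
    by_entity = defaultdict(list)
    for bundle in sorted(qc_dir.iterdir()):
        m = read_bundle(bundle)
        entity = m.annotations["entity"].iloc[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            programs = run_nmf_grid(m, cfg)
        by_entity[entity].append((bundle.name, programs))
        print(f"{bundle.name}: {len(programs)} programs")

    rows = []
    for entity, study_programs in by_entity.items():
        pooled = [p for _, programs in study_programs for p in programs]
        robust = select_robust(pooled, cfg)
        write_programs_json(robust, ROOT / "scratch" / f"programs_{entity}.json",
                            meta={"entity": entity})
        rows.append({"entity": entity, "programs": len(pooled),
                     "robust": len(robust.programs)})
        print(f"{entity}: {len(robust.programs)}/{len(pooled)} programs robust")
    out = ROOT / "results" / "03_program_counts.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"counts -> {out}")


if __name__ == "__main__":
    main()
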