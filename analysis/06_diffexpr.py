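#!/usr/bin/env python
"""Differential expression, enrichment, and consensus malignancy labels
(run after 01_simulate.py).

Pools one malignant and one inflammatory study (shared gene universe),
runs Wilcoxon rank-sum DE between the two entities on log-normalized
expression, feeds the top up-regulated genes into hypergeometric
enrichment against the planted program gene sets, and derives consensus
malignancy labels from two noisy synthetic copy-number callers.
"""

import dataclasses
from pathlib import Path

import pandas as pd
import scipy.sparse as sp

from mpkit.diffexpr import (
    consensus_counts,
    consensus_malignancy,
    hypergeom_enrich,
    wilcoxon_deg,
)
from mpkit.io import read_bundle
from mpkit.matrix import ExpressionMatrix
from mpkit.qc import lognormalize
from mpkit.simulate import caller_calls, read_truth

ROOT = Path(__file__).resolve().parent.parent


def pool_studies(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    assert a.gene_ids == b.gene_ids
    return ExpressionMatrix(
        values=sp.hstack([a.values, b.values]),
        gene_ids=a.gene_ids,
        cell_ids=a.cell_ids + b.cell_ids,
        annotations=pd.concat([a.annotations, b.annotations]),
    )


def main() -> None:
    data_dir = ROOT / "scratch" / "data"
    if not data_dir.exists():
        raise SystemExit("no scratch/data — run analysis/01_simulate.py first")
    truth = read_truth(data_dir / "truth")

    m = pool_studies(read_bundle(data_dir / "CRC_malignant_s1"),
                     read_bundle(data_dir / "IBD_epithelial_s1"))
    norm = lognormalize(m)
    ann = norm.annotations
    ga = list(ann.index[ann["entity"] == "CRC_malignant"])
    gb = list(ann.index[ann["entity"] == "IBD_epithelial"])
    degs = wilcoxon_deg(norm, ga, gb)
    deg_df = pd.DataFrame([dataclasses.asdict(d) for d in degs])
    deg_df.to_csv(ROOT / "results" / "06_deg_malignant_vs_ibd.tsv",
                  sep="\t", index=False, float_format="%.4g")
    n_sig = int((deg_df.fdr < 0.05).sum())
    print(f"{n_sig}/{len(deg_df)} genes at FDR < 0.05 between entities")

    up = deg_df[(deg_df.fdr < 0.05) & (deg_df.direction == "up")]
    query = list(up.sort_values("fdr").head(100).gene_id)
    terms = {f"{e}|program{i}": set(genes)
             for e, progs in truth.planted_programs.items()
             for i, genes in enumerate(progs)}
    enr = hypergeom_enrich(query, terms, norm.gene_ids)
    enr_df = pd.DataFrame([dataclasses.asdict(e) for e in enr]) \
        .sort_values("p_value")
    enr_df.to_csv(ROOT / "results" / "06_enrichment_up_in_malignant.tsv",
                  sep="\t", index=False, float_format="%.4g")
    print("top enriched planted programs among up-in-malignant genes:")
    print(enr_df.head(4)[["term_id", "overlap_count", "fdr", "significant"]]
          .to_string(index=False))

    # two imperfect CNV callers, consensus by intersection
    calls_a = caller_calls(truth, flip_rate=0.02, uncallable_rate=0.05, seed=11)
    calls_b = caller_calls(truth, flip_rate=0.05, uncallable_rate=0.02, seed=12)
    labels = consensus_malignancy(calls_a, calls_b)
    counts = consensus_counts(labels)
    pd.DataFrame([dataclasses.asdict(l) for l in labels]).to_csv(
        ROOT / "results" / "06_consensus_malignancy.tsv", sep="\t", index=False)
    print(f"consensus labels: {counts} "
          f"({counts['malignant'] + counts['nonmalignant']} high-confidence)")


if __name__ == "__main__":
    main()
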