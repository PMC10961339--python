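#!/usr/bin/env python
"""Cluster robust programs into Meta Programs and compare entities
(run after 03_programs.py).

Founder-based agglomeration (growth threshold: strictly more than 10
shared genes with the cluster consensus) per entity, then pairwise MP
gene-set overlaps across entities and against the planted truth. Writes MP
gene sets (GMT) and the overlap table to results/.
"""

from pathlib import Path

import pandas as pd

from mpkit.cli import read_programs_json
from mpkit.io import write_gmt
from mpkit.metaprograms import MPConfig, cluster_programs, compare_mps, jaccard
from mpkit.simulate import read_truth

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    truth = read_truth(ROOT / "scratch" / "data" / "truth")
    cfg = MPConfig()
    mps_by_entity = {}
    gmt = {}
    for path in sorted((ROOT / "scratch").glob("programs_*.json")):
        entity = path.stem.removeprefix("programs_")
        robust = read_programs_json(path)
        mps, unassigned = cluster_programs(robust, cfg)
        mps_by_entity[entity] = mps
        for mp in mps:
            gmt[f"{entity}|{mp.mp_id}"] = mp.mp_genes
            best = max(jaccard(mp.mp_genes, p) for p in truth.planted_programs[entity])
            print(f"{entity} {mp.mp_id}: {len(mp.members)} members, "
                  f"best Jaccard to a planted program {best:.2f}")
        print(f"{entity}: {len(mps)} meta-programs, {len(unassigned)} unassigned")
    write_gmt(gmt, ROOT / "results" / "04_mp_genes.gmt")

    rows = []
    entities = sorted(mps_by_entity)
    for i, a in enumerate(entities):
        for b in entities[i + 1:]:
            for mp_a in mps_by_entity[a]:
                for mp_b in mps_by_entity[b]:
                    ov = compare_mps(mp_a, mp_b)
                    rows.append({"entity_a": a, "mp_a": mp_a.mp_id,
                                 "entity_b": b, "mp_b": mp_b.mp_id,
                                 "shared_genes": ov.overlap_count,
                                 "overlap_pct": round(100 * ov.overlap_fraction, 1)})
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "04_mp_overlaps.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table[table.shared_genes > 0].to_string(index=False))
    print(f"MP gene sets -> results/04_mp_genes.gmt; overlaps -> {out}")


if __name__ == "__main__":
    main()
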