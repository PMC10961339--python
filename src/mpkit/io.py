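"""Readers and writers for the interchange formats.

A *bundle* is a directory holding one study: ``matrix.mtx`` (Matrix-Market
coordinate triplets, genes as rows, 1-based per the format), ``genes.tsv``,
``cells.tsv`` (cell_id plus annotation columns) and ``metadata.json``
(layer state, tool version, config hash, seed). Gene sets travel as GMT;
configuration as YAML with every default materialized on write.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from .activity import AUCellConfig
from .matrix import ExpressionMatrix, MatrixValidationError
from .metaprograms import MPConfig
from .nmf import NMFConfig
from .qc import QCConfig
from .simulate import SimulationConfig


class BundleError(ValueError):
    pass


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_bundle(m: ExpressionMatrix, path: str | Path,
                 extra_metadata: dict | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.values))
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(path / "genes.tsv", sep="\t", index=False)
    cells = m.annotations.reset_index()
    cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    meta = {
        "layer_state": m.layer_state,
        "n_genes": m.n_genes,
        "n_cells": m.n_cells,
        "tool_version": __version__,
    }
    meta.update(extra_metadata or {})
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_bundle(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    mtx_path = path / "matrix.mtx"
    for p in (mtx_path, path / "genes.tsv", path / "cells.tsv"):
        if not p.exists():
            raise BundleError(f"missing bundle file: {p}")
    values = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    if "gene_id" not in genes.columns or "cell_id" not in cells.columns:
        raise BundleError("genes.tsv needs a gene_id column, cells.tsv a cell_id column")
    if len(genes) != values.shape[0]:
        raise BundleError(
            f"dimension mismatch: {len(genes)} genes in table, {values.shape[0]} matrix rows"
        )
    if len(cells) != values.shape[1]:
        raise BundleError(
            f"dimension mismatch: {len(cells)} cells in table, {values.shape[1]} matrix columns"
        )
    if genes["gene_id"].duplicated().any():
        raise BundleError("duplicate gene IDs in genes.tsv")
    if cells["cell_id"].duplicated().any():
        raise BundleError("duplicate cell IDs in cells.tsv")
    if values.nnz and values.data.min() < 0:
        raise BundleError("negative values in matrix.mtx")
    layer_state = "raw"
    meta_path = path / "metadata.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            layer_state = json.load(fh).get("layer_state", "raw")
    ann = cells.set_index("cell_id")
    try:
        return ExpressionMatrix(
            values=values,
            gene_ids=list(genes["gene_id"]),
            cell_ids=list(cells["cell_id"].astype(str)),
            annotations=ann,
            layer_state=layer_state,
        )
    except MatrixValidationError as exc:
        raise BundleError(str(exc)) from exc


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered term → gene-list map."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BundleError(f"GMT line {lineno}: need name, description, >=1 gene")
            name, genes = parts[0], parts[2:]
            if name in out:
                raise BundleError(f"duplicate GMT term name {name!r}")
            seen: list[str] = []
            dupes = 0
            for g in genes:
                if g in seen:
                    dupes += 1
                else:
                    seen.append(g)
            if dupes:
                warnings.warn(
                    f"GMT term {name!r}: {dupes} duplicated genes removed",
                    stacklevel=2,
                )
            out[name] = seen
    return out


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "mpkit") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")


@dataclass
class RunConfig:
    """Aggregate configuration of the whole pipeline, YAML round-trippable."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    nmf: NMFConfig = field(default_factory=NMFConfig)
    mp: MPConfig = field(default_factory=MPConfig)
    aucell: AUCellConfig = field(default_factory=AUCellConfig)

    def to_dict(self) -> dict:
        return {
            "simulate": self.simulate.to_dict(),
            "qc": dataclasses.asdict(self.qc),
            "nmf": dataclasses.asdict(self.nmf),
            "mp": dataclasses.asdict(self.mp),
            "aucell": dataclasses.asdict(self.aucell),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {"simulate", "qc", "nmf", "mp", "aucell"}
        unknown = set(d) - sections
        if unknown:
            raise BundleError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, typ in (("qc", QCConfig), ("nmf", NMFConfig),
                          ("mp", MPConfig), ("aucell", AUCellConfig)):
            if name in d:
                known = {f.name for f in dataclasses.fields(typ)}
                bad = set(d[name]) - known
                if bad:
                    raise BundleError(f"unknown keys in {name!r} section: {sorted(bad)}")
                kwargs[name] = typ(**d[name])
        if "simulate" in d:
            kwargs["simulate"] = SimulationConfig.from_dict(d["simulate"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        return config_hash(self.to_dict())
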