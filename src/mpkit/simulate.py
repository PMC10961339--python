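"""Multi-study single-cell count simulator with planted gene programs.

Cells are non-negative mixtures of sparse gene programs: each disease
entity carries a fixed panel of programs (gene sets with log-normal
coefficients), every cell draws a Dirichlet usage vector over its entity's
programs, and counts come from a Poisson or negative-binomial noise model
around ``library_size * normalize(signature @ usage)`` plus a small uniform
background. Programs can be partially shared between entities with a
controlled gene-overlap fraction, which is what the meta-program pipeline
downstream is supposed to rediscover.

Overlap construction: each configured entity pair is assigned one dedicated
program slot (round-robin over slots) and the two entities' programs at
that slot share exactly ``round(fraction * program_size)`` genes. Hosting
each pair's overlap on its own slot keeps arbitrary overlap maps feasible —
a single program cannot owe more shared genes than it has — and the chosen
slots are recorded in the truth so recovery tests know which program pairs
to compare.

A single global seed drives a hierarchical random stream (one child stream
per study) so that adding a study to the configuration does not perturb the
draws of earlier studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import RAW, ExpressionMatrix

NOISE_MODELS = ("poisson", "negative_binomial")

DEFAULT_CELL_TYPES = ("epithelial", "T_cell", "B_cell", "myeloid", "fibroblast")
DEFAULT_TISSUES = ("tumor", "adjacent_normal", "inflamed", "normal")
DEFAULT_STAGES = ("I", "II", "III", "IV")


class SimulationConfigError(ValueError):
    """Configuration violates an invariant; the message names the field."""


def _default_label_distributions(entity: str) -> dict[str, dict[str, float]]:
    """Built-in per-entity categorical label distributions.

    Malignant entities are dominated by epithelial cells in tumor tissue,
    non-malignant tumor-adjacent entities by epithelial/stromal cells, and
    inflammatory entities by a mixed epithelial/immune pool in inflamed
    tissue. Stages are drawn uniformly-ish so stage-wise comparisons have
    all levels populated.
    """
    name = entity.lower()
    malignant = "malignant" in name and "non" not in name
    if malignant:
        cell_type = {"epithelial": 0.85, "T_cell": 0.05, "B_cell": 0.02,
                     "myeloid": 0.05, "fibroblast": 0.03}
        tissue = {"tumor": 0.8, "adjacent_normal": 0.2, "inflamed": 0.0, "normal": 0.0}
    elif "malignant" in name:  # non-malignant arm of a tumor entity
        cell_type = {"epithelial": 0.7, "T_cell": 0.1, "B_cell": 0.05,
                     "myeloid": 0.05, "fibroblast": 0.1}
        tissue = {"tumor": 0.35, "adjacent_normal": 0.65, "inflamed": 0.0, "normal": 0.0}
    elif any(tag in name for tag in ("ibd", "inflam", "colitis")):
        cell_type = {"epithelial": 0.5, "T_cell": 0.25, "B_cell": 0.15,
                     "myeloid": 0.07, "fibroblast": 0.03}
        tissue = {"tumor": 0.0, "adjacent_normal": 0.0, "inflamed": 0.7, "normal": 0.3}
    else:
        cell_type = {k: 1 / len(DEFAULT_CELL_TYPES) for k in DEFAULT_CELL_TYPES}
        tissue = {k: 1 / len(DEFAULT_TISSUES) for k in DEFAULT_TISSUES}
    stage = {"I": 0.2, "II": 0.3, "III": 0.3, "IV": 0.2}
    return {"cell_type": cell_type, "tissue": tissue, "stage": stage}


@dataclass
class SimulationConfig:
    entities: list[str] = field(default_factory=lambda: ["entity_A", "entity_B"])
    n_studies_per_entity: int = 3
    n_genes: int = 800
    n_cells_per_study: int = 400
    n_programs_per_entity: int = 4
    program_size: int = 50
    cross_entity_overlap: dict[tuple[str, str], float] = field(default_factory=dict)
    usage_concentration: float = 0.5
    library_size_mean: float = 2000.0
    noise_model: str = "negative_binomial"
    nb_dispersion: float = 10.0
    background_fraction: float = 0.05
    label_distributions: dict[str, dict[str, dict[str, float]]] | None = None
    malignant_entities: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.entities or len(set(self.entities)) != len(self.entities):
            raise SimulationConfigError("entities: must be a non-empty list of unique labels")
        for fname in ("n_studies_per_entity", "n_genes", "n_cells_per_study",
                      "n_programs_per_entity", "program_size"):
            if int(getattr(self, fname)) <= 0:
                raise SimulationConfigError(f"{fname}: must be a positive integer")
        if self.program_size * self.n_programs_per_entity > self.n_genes:
            raise SimulationConfigError(
                "n_genes: program_size * n_programs_per_entity exceeds n_genes"
            )
        for pair, f in self.cross_entity_overlap.items():
            a, b = pair
            if a not in self.entities or b not in self.entities:
                raise SimulationConfigError(
                    f"cross_entity_overlap: unknown entity in pair {pair}"
                )
            if not (0.0 <= f <= 1.0):
                raise SimulationConfigError(
                    f"cross_entity_overlap: fraction for {pair} outside [0, 1]"
                )
        if self.usage_concentration < 0:
            raise SimulationConfigError("usage_concentration: must be non-negative")
        if self.library_size_mean <= 0:
            raise SimulationConfigError("library_size_mean: must be positive")
        if self.noise_model not in NOISE_MODELS:
            raise SimulationConfigError(
                f"noise_model: must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.nb_dispersion <= 0:
            raise SimulationConfigError("nb_dispersion: must be positive")
        if not (0.0 <= self.background_fraction < 1.0):
            raise SimulationConfigError("background_fraction: must be in [0, 1)")
        # the round-robin slot assignment needs a free slot per overlapping pair
        n_pairs = sum(1 for f in self.cross_entity_overlap.values() if f > 0)
        if n_pairs > self.n_programs_per_entity:
            raise SimulationConfigError(
                "cross_entity_overlap: more overlapping pairs than program slots"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cross_entity_overlap"] = {
            f"{a}|{b}": f for (a, b), f in self.cross_entity_overlap.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimulationConfigError(f"unknown config keys: {sorted(unknown)}")
        overlap = {}
        for key, f in d.get("cross_entity_overlap", {}).items():
            a, b = key.split("|") if isinstance(key, str) else key
            overlap[(a, b)] = float(f)
        d["cross_entity_overlap"] = overlap
        return cls(**d)


@dataclass(eq=False)
class SyntheticTruth:
    """Planted ground truth: program gene sets, usage weights, labels."""

    planted_programs: dict[str, list[list[str]]]  # entity -> programs, genes ranked
    usage: dict[str, np.ndarray]                  # study_id -> (n_cells, P) weights
    cell_labels: pd.DataFrame                     # indexed by cell_id
    overlap_assignments: dict[str, dict]          # "A|B" -> {slot, n_shared, shared_genes}
    config: SimulationConfig

    def studies(self) -> list[str]:
        return list(self.usage)

    def equals(self, other: "SyntheticTruth", atol: float = 1e-9) -> bool:
        if self.planted_programs != other.planted_programs:
            return False
        if self.overlap_assignments != other.overlap_assignments:
            return False
        if self.config != other.config:
            return False
        if list(self.usage) != list(other.usage):
            return False
        for sid in self.usage:
            if not np.allclose(self.usage[sid], other.usage[sid], atol=atol):
                return False
        try:
            pd.testing.assert_frame_equal(
                self.cell_labels, other.cell_labels, check_dtype=False
            )
        except AssertionError:
            return False
        return True


def _allocate_programs(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign disjoint gene pools to programs, carving out shared blocks.

    Returns (programs: entity -> list of gene-index arrays, assignments).
    """
    pool = list(rng.permutation(cfg.n_genes))
    shared_blocks: dict[tuple[str, int], list[int]] = {}
    assignments: dict[str, dict] = {}
    overlapping = [(pair, f) for pair, f in cfg.cross_entity_overlap.items() if f > 0]
    for j, ((a, b), f) in enumerate(overlapping):
        slot = j % cfg.n_programs_per_entity
        n_shared = int(round(f * cfg.program_size))
        block = [pool.pop() for _ in range(n_shared)]
        shared_blocks.setdefault((a, slot), []).extend(block)
        shared_blocks.setdefault((b, slot), []).extend(block)
        assignments[f"{a}|{b}"] = {"slot": slot, "n_shared": n_shared, "genes": block}
    for pair, f in cfg.cross_entity_overlap.items():
        if f == 0:
            assignments[f"{pair[0]}|{pair[1]}"] = {"slot": None, "n_shared": 0, "genes": []}
    programs: dict[str, list[np.ndarray]] = {}
    for entity in cfg.entities:
        ent_programs = []
        for slot in range(cfg.n_programs_per_entity):
            genes = list(shared_blocks.get((entity, slot), []))
            if len(genes) > cfg.program_size:
                raise SimulationConfigError(
                    f"cross_entity_overlap: program slot {slot} of {entity} "
                    f"over-committed ({len(genes)} shared genes > program_size)"
                )
            n_fill = cfg.program_size - len(genes)
            if n_fill > len(pool):
                raise SimulationConfigError(
                    "n_genes: too small to host all planted programs disjointly"
                )
            genes.extend(pool.pop() for _ in range(n_fill))
            ent_programs.append(np.array(genes, dtype=int))
        programs[entity] = ent_programs
    return programs, assignments


def _is_malignant_entity(entity: str, cfg: SimulationConfig) -> bool:
    if cfg.malignant_entities is not None:
        return entity in cfg.malignant_entities
    name = entity.lower()
    return "malignant" in name and "non" not in name


def generate(config: SimulationConfig) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """Simulate one count matrix per (entity, study) plus full ground truth.

    Deterministic: identical (config, seed) pairs reproduce identical output.
    """
    config.validate()
    cfg = config
    # explicit spawn keys: stream identity depends only on (entity, study)
    # position, so adding studies or entities never perturbs earlier draws
    struct_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    program_idx, assignments = _allocate_programs(cfg, struct_rng)

    # log-normal coefficients give graded "top gene" rankings per program
    signatures: dict[str, np.ndarray] = {}
    planted: dict[str, list[list[str]]] = {}
    for entity in cfg.entities:
        S = np.zeros((cfg.n_genes, cfg.n_programs_per_entity))
        ent_lists = []
        for p, genes in enumerate(program_idx[entity]):
            coefs = struct_rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
            S[genes, p] = coefs
            order = np.argsort(-coefs, kind="stable")
            ent_lists.append([gene_ids[genes[i]] for i in order])
        S /= S.sum(axis=0, keepdims=True)
        signatures[entity] = S
        planted[entity] = ent_lists

    # record gene IDs (allocation worked on integer indices)
    for rec in assignments.values():
        rec["genes"] = sorted(gene_ids[i] for i in rec["genes"])

    background = np.full(cfg.n_genes, 1.0 / cfg.n_genes)
    matrices: dict[str, ExpressionMatrix] = {}
    usage_truth: dict[str, np.ndarray] = {}
    label_rows = []

    for e_idx, entity in enumerate(cfg.entities):
        dists = None
        if cfg.label_distributions is not None:
            dists = cfg.label_distributions.get(entity)
        if dists is None:
            dists = _default_label_distributions(entity)
        malignant = _is_malignant_entity(entity, cfg)
        for j in range(cfg.n_studies_per_entity):
            study_id = f"{entity}_s{j + 1}"
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(1, e_idx, j))
            )
            label_rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(2, e_idx, j))
            )
            P = cfg.n_programs_per_entity
            n = cfg.n_cells_per_study
            if cfg.usage_concentration == 0:
                usage = np.zeros((n, P))
                usage[np.arange(n), rng.integers(0, P, size=n)] = 1.0
            else:
                usage = rng.dirichlet([cfg.usage_concentration] * P, size=n)
            profile = signatures[entity] @ usage.T  # genes x cells
            profile = (1 - cfg.background_fraction) * profile \
                + cfg.background_fraction * background[:, None]
            lam = cfg.library_size_mean * profile
            if cfg.noise_model == "poisson":
                counts = rng.poisson(lam)
            else:
                r = cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + lam))
            cell_ids = [f"{study_id}_c{i:04d}" for i in range(n)]
            for key in ("cell_type", "tissue", "stage"):
                levels = list(dists[key])
                probs = np.array([dists[key][lv] for lv in levels], dtype=float)
                probs = probs / probs.sum()
                drawn = label_rng.choice(levels, size=n, p=probs)
                if key == "cell_type":
                    cell_type = drawn
                elif key == "tissue":
                    tissue = drawn
                else:
                    stage = drawn
            ann = pd.DataFrame(
                {
                    "study": study_id,
                    "entity": entity,
                    "cell_type": cell_type,
                    "tissue": tissue,
                    "stage": stage,
                    "malignant": malignant,
                },
                index=pd.Index(cell_ids, name="cell_id"),
            )
            matrices[study_id] = ExpressionMatrix(
                values=sp.csr_matrix(counts), gene_ids=gene_ids,
                cell_ids=cell_ids, annotations=ann, layer_state=RAW,
            )
            usage_truth[study_id] = usage
            label_rows.append(ann)

    truth = SyntheticTruth(
        planted_programs=planted,
        usage=usage_truth,
        cell_labels=pd.concat(label_rows),
        overlap_assignments=assignments,
        config=cfg,
    )
    return matrices, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write planted programs (GMT), cell labels (TSV), usage (TSV), config (JSON)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "planted_programs.gmt", "w") as fh:
        for entity, programs in truth.planted_programs.items():
            for p, genes in enumerate(programs):
                fh.write("\t".join([f"{entity}|program{p}", "planted"] + genes) + "\n")
    truth.cell_labels.to_csv(path / "cell_labels.tsv", sep="\t")
    usage_frames = []
    for sid, u in truth.usage.items():
        df = pd.DataFrame(u, columns=[f"program{p}" for p in range(u.shape[1])])
        df.insert(0, "study", sid)
        usage_frames.append(df)
    pd.concat(usage_frames, ignore_index=True).to_csv(
        path / "usage.tsv", sep="\t", index=False
    )
    with open(path / "truth.json", "w") as fh:
        json.dump(
            {
                "config": truth.config.to_dict(),
                "overlap_assignments": truth.overlap_assignments,
            },
            fh,
            indent=2,
        )


def read_truth(path: str | Path) -> SyntheticTruth:
    """Inverse of :func:`write_truth`; ``read_truth(write_truth(t)) == t``."""
    path = Path(path)
    with open(path / "truth.json") as fh:
        blob = json.load(fh)
    cfg = SimulationConfig.from_dict(blob["config"])
    planted: dict[str, list[list[str]]] = {}
    with open(path / "planted_programs.gmt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            entity = parts[0].split("|")[0]
            planted.setdefault(entity, []).append(parts[2:])
    labels = pd.read_csv(path / "cell_labels.tsv", sep="\t", index_col="cell_id")
    usage_df = pd.read_csv(path / "usage.tsv", sep="\t")
    usage = {
        sid: grp.drop(columns="study").to_numpy()
        for sid, grp in usage_df.groupby("study", sort=False)
    }
    return SyntheticTruth(
        planted_programs=planted,
        usage=usage,
        cell_labels=labels,
        overlap_assignments=blob["overlap_assignments"],
        config=cfg,
    )


def caller_calls(
    truth: SyntheticTruth,
    flip_rate: float = 0.0,
    uncallable_rate: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Emit a synthetic copy-number-caller labelling from the truth.

    Stands in for CNV-based malignancy callers when testing the consensus
    rule: true malignant flags are flipped with ``flip_rate`` and masked to
    ``uncallable`` with ``uncallable_rate``.
    """
    rng = np.random.default_rng(seed)
    calls = np.where(truth.cell_labels["malignant"], "malignant", "nonmalignant")
    n = len(calls)
    flip = rng.random(n) < flip_rate
    flipped = np.where(calls == "malignant", "nonmalignant", "malignant")
    calls = np.where(flip, flipped, calls)
    calls = np.where(rng.random(n) < uncallable_rate, "uncallable", calls)
    return pd.Series(calls, index=truth.cell_labels.index, name="call")
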