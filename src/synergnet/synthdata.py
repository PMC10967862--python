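"""Synthetic dataset generator.

Emulates every input the pipeline consumes — an annotated interaction
network, per-cell-line profiles, a GO-embedding table, a drug library with
fingerprints and target profiles, and a labeled synergy table — with a
planted, learnable label rule: a pair is synergistic when its two drugs'
target sets jointly cover enough distinct members of the cell line's
dysregulated gene module while keeping their mutual target overlap below a
redundancy cap; labels are then flipped at a configurable noise rate.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from synergnet.augment import (
    DrugLibrary,
    Fingerprint,
    SynergyInstance,
    read_synergy_table,
    write_synergy_table,
)
from synergnet.features import (
    GO_DIM,
    CNV_CATEGORIES,
    MUTATION_TYPES,
    SCORE_MAX,
    SCORE_MIN,
    CellLineProfile,
    DrugRecord,
    GOEmbeddingTable,
    build_featured_graph,
)
from synergnet.graphio import PPINetwork, canonical_edge, read_network, write_network
from synergnet.reduce import ReducedGraph, reduce_graph

__all__ = ["SynthConfig", "SynthBundle", "make_ppi", "make_drugs",
           "make_cell_lines", "make_labels", "make_dataset", "load_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    # network
    n_proteins: int = 120
    mean_degree: float = 6.0
    druggable_fraction: float = 0.75
    # drugs
    n_drugs: int = 24
    n_families: int = 6
    targets_per_drug: tuple[int, int] = (4, 7)
    fingerprint_width: int = 256
    fingerprint_bits: int = 64
    family_bit_flip: float = 0.08
    family_target_keep: float = 0.85
    extra_targets_max: int = 3
    # cell lines
    n_cell_lines: int = 6
    module_size: int = 20
    expression_sparsity: float = 0.10
    cnv_rate: float = 0.05
    mutation_rate: float = 0.05
    # labels
    n_pairs: int = 600
    synergy_fraction: float = 0.766
    overlap_cap: int | None = None
    label_noise: float = 0.05
    # misc
    go_dim: int = GO_DIM
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_drugs, self.n_cell_lines,
               self.n_pairs) <= 0:
            raise ValueError("all counts must be positive")
        for p in (self.druggable_fraction, self.expression_sparsity,
                  self.cnv_rate, self.mutation_rate, self.label_noise,
                  self.synergy_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.go_dim != GO_DIM:
            raise ValueError(f"go_dim is fixed at {GO_DIM}")
        if self.mean_degree >= self.n_proteins:
            raise ValueError("mean degree infeasible for node count")


@dataclass
class SynthBundle:
    """A complete synthetic dataset plus generator metadata."""

    config: SynthConfig
    ppi: PPINetwork
    profiles: dict[str, CellLineProfile]
    go_table: GOEmbeddingTable
    library: DrugLibrary
    originals: list[SynergyInstance]
    modules: dict[str, frozenset[str]]  # cell line -> dysregulated module
    _reduced_cache: dict[tuple[str, str, str], ReducedGraph] = field(
        default_factory=dict, repr=False
    )

    def featured_graph(self, inst: SynergyInstance):
        return build_featured_graph(
            self.ppi,
            self.profiles[inst.cell_line],
            self.library.records[inst.drug_a],
            self.library.records[inst.drug_b],
            self.go_table,
            label=inst.label,
        )

    def reduced_graph(self, inst: SynergyInstance) -> ReducedGraph:
        key = inst.pair_key
        if key not in self._reduced_cache:
            self._reduced_cache[key] = reduce_graph(self.featured_graph(inst))
        return self._reduced_cache[key]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _protein_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i:0{width}d}" for i in range(n)]


def make_ppi(cfg: SynthConfig, rng: np.random.Generator | None = None
             ) -> PPINetwork:
    """Degree-heterogeneous connected random graph (preferential
    attachment) with druggable flags at the configured fraction."""
    rng = rng or np.random.default_rng(cfg.seed)
    m = max(1, round(cfg.mean_degree / 2))
    if m >= cfg.n_proteins:
        raise ValueError("mean degree infeasible for node count")
    g = nx.barabasi_albert_graph(
        cfg.n_proteins, m, seed=int(rng.integers(2**31))
    )
    names = _protein_names(cfg.n_proteins)
    druggable_flags = rng.random(cfg.n_proteins) < cfg.druggable_fraction
    druggable = {names[i]: bool(druggable_flags[i])
                 for i in range(cfg.n_proteins)}
    edges = {canonical_edge(names[u], names[v]) for u, v in g.edges()}
    confidence = {e: float(0.7 + 0.3 * rng.random()) for e in sorted(edges)}
    return PPINetwork(druggable=druggable, edges=edges, confidence=confidence)


def make_drugs(cfg: SynthConfig, ppi: PPINetwork,
               rng: np.random.Generator | None = None) -> DrugLibrary:
    """Drug library organized in families of similar drugs.

    Members of a family share most fingerprint bits and most targets, so
    the similarity filter has realistic pass/fail structure; association
    scores are uniform in [150, 999].
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    druggable_nodes = sorted(n for n, f in ppi.druggable.items() if f)
    if not druggable_nodes:
        raise ValueError("network has no druggable nodes")
    width = len(str(cfg.n_drugs))
    lo, hi = cfg.targets_per_drug

    proto_bits, proto_targets = [], []
    for _f in range(cfg.n_families):
        proto_bits.append(frozenset(
            rng.choice(cfg.fingerprint_width, size=cfg.fingerprint_bits,
                       replace=False).tolist()
        ))
        size = int(rng.integers(lo, hi + 1))
        proto_targets.append(frozenset(
            rng.choice(druggable_nodes, size=min(size, len(druggable_nodes)),
                       replace=False).tolist()
        ))

    records: dict[str, DrugRecord] = {}
    fingerprints: dict[str, Fingerprint] = {}
    for i in range(cfg.n_drugs):
        drug_id = f"D{i:0{width}d}"
        fam = i % cfg.n_families
        bits = {
            b for b in proto_bits[fam] if rng.random() > cfg.family_bit_flip
        }
        n_extra = max(1, int(cfg.family_bit_flip * cfg.fingerprint_bits))
        bits.update(rng.choice(cfg.fingerprint_width, size=n_extra,
                               replace=False).tolist())
        fingerprints[drug_id] = Fingerprint(
            bits=frozenset(int(b) for b in bits), width=cfg.fingerprint_width
        )
        targets = {
            t for t in sorted(proto_targets[fam])  # stable iteration order
            if rng.random() < cfg.family_target_keep
        }
        n_extra = int(rng.integers(0, cfg.extra_targets_max + 1))
        targets.update(
            str(t) for t in rng.choice(druggable_nodes, size=n_extra,
                                       replace=False)
        )
        if not targets:
            targets.add(str(rng.choice(sorted(proto_targets[fam]))))
        associations = {
            t: float(rng.uniform(SCORE_MIN, SCORE_MAX)) for t in sorted(targets)
        }
        records[drug_id] = DrugRecord(
            drug_id=drug_id, smiles=None, associations=associations
        )
    return DrugLibrary(
        records=records,
        node_order=sorted(ppi.druggable),
        fingerprints=fingerprints,
    )


def make_cell_lines(
    cfg: SynthConfig, ppi: PPINetwork,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, CellLineProfile], dict[str, frozenset[str]]]:
    """Profiles plus the per-cell-line dysregulated gene module.

    Module genes are dysregulated (expression +/-1); a sparse fraction of
    the remaining genes carries +/-1 noise; CNV and mutation assignments
    are independent sparse draws.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    nodes = sorted(ppi.druggable)
    width = len(str(cfg.n_cell_lines))
    profiles: dict[str, CellLineProfile] = {}
    modules: dict[str, frozenset[str]] = {}
    for c in range(cfg.n_cell_lines):
        cell_id = f"C{c:0{width}d}"
        module = frozenset(
            str(x) for x in rng.choice(
                nodes, size=min(cfg.module_size, len(nodes)), replace=False
            )
        )
        expression: dict[str, int] = {}
        cnv: dict[str, str] = {}
        mutations: dict[str, frozenset[str]] = {}
        for gene in nodes:
            if gene in module or rng.random() < cfg.expression_sparsity:
                expression[gene] = int(rng.choice((-1, 1)))
            if rng.random() < cfg.cnv_rate:
                cnv[gene] = str(rng.choice(CNV_CATEGORIES[1:]))
            if rng.random() < cfg.mutation_rate:
                k = int(rng.integers(1, 3))
                mutations[gene] = frozenset(
                    str(t) for t in rng.choice(MUTATION_TYPES, size=k,
                                               replace=False)
                )
        profiles[cell_id] = CellLineProfile(
            cell_line_id=cell_id, expression=expression, cnv=cnv,
            mutations=mutations,
        )
        modules[cell_id] = module
    return profiles, modules


def make_labels(
    cfg: SynthConfig,
    library: DrugLibrary,
    modules: dict[str, frozenset[str]],
    rng: np.random.Generator | None = None,
) -> list[SynergyInstance]:
    """Sample drug pairs and label them with the planted rule.

    The coverage threshold is placed at the (1 - synergy_fraction)
    quantile of the sampled pairs' coverage scores, so the class prior
    tracks the configured fraction; labels are flipped at the noise rate.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    drug_ids = library.drug_ids
    cell_ids = sorted(modules)
    cap = cfg.overlap_cap
    if cap is None:
        cap = cfg.targets_per_drug[1]  # effectively non-binding default

    pairs: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    attempts = 0
    while len(pairs) < cfg.n_pairs and attempts < 50 * cfg.n_pairs:
        attempts += 1
        a, b = rng.choice(drug_ids, size=2, replace=False)
        cell = str(rng.choice(cell_ids))
        key = (*sorted((str(a), str(b))), cell)
        if key in seen:
            continue
        seen.add(key)
        pairs.append((str(a), str(b), cell))

    coverages, overlaps = [], []
    for a, b, cell in pairs:
        ta = library.records[a].targets
        tb = library.records[b].targets
        coverages.append(len((ta | tb) & modules[cell]))
        overlaps.append(len(ta & tb))
    # sub-integer jitter makes the coverage scale continuous, so the
    # class-prior quantile can cut inside a tied coverage stratum
    scores = np.asarray(coverages, dtype=float) + rng.random(len(pairs))
    threshold = float(np.quantile(scores, 1.0 - cfg.synergy_fraction))
    out = []
    for (a, b, cell), score, ov in zip(pairs, scores, overlaps):
        synergistic = score >= threshold and ov <= cap
        if rng.random() < cfg.label_noise:
            synergistic = not synergistic
        out.append(SynergyInstance(
            drug_a=a, drug_b=b, cell_line=cell,
            label="synergy" if synergistic else "antagonism",
        ))
    return out


def make_dataset(cfg: SynthConfig, out_dir: str | Path | None = None
                 ) -> SynthBundle:
    """Generate the full bundle; optionally write every external-interface
    file plus a manifest with config, seed, and checksums."""
    ppi = make_ppi(cfg, np.random.default_rng(cfg.seed))
    library = make_drugs(cfg, ppi, np.random.default_rng(cfg.seed + 1))
    profiles, modules = make_cell_lines(
        cfg, ppi, np.random.default_rng(cfg.seed + 2)
    )
    go_rng = np.random.default_rng(cfg.seed + 4)
    go_table = GOEmbeddingTable({
        gene: go_rng.normal(0.0, 1.0, size=GO_DIM)
        for gene in sorted(ppi.druggable)
    })
    originals = make_labels(
        cfg, library, modules, np.random.default_rng(cfg.seed + 3)
    )
    bundle = SynthBundle(
        config=cfg, ppi=ppi, profiles=profiles, go_table=go_table,
        library=library, originals=originals, modules=modules,
    )
    if out_dir is not None:
        write_dataset(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(bundle: SynthBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(bundle.ppi, out / "edges.tsv", out / "nodes.tsv")
    bundle.go_table.to_tsv(out / "go_embeddings.tsv")
    with open(out / "expression.tsv", "w") as fh:
        for cell, prof in sorted(bundle.profiles.items()):
            for gene, val in sorted(prof.expression.items()):
                fh.write(f"{cell}\t{gene}\t{val:+d}\n")
    with open(out / "cnv.tsv", "w") as fh:
        for cell, prof in sorted(bundle.profiles.items()):
            for gene, cat in sorted(prof.cnv.items()):
                fh.write(f"{cell}\t{gene}\t{cat}\n")
    with open(out / "mutations.tsv", "w") as fh:
        for cell, prof in sorted(bundle.profiles.items()):
            for gene, types in sorted(prof.mutations.items()):
                for t in sorted(types):
                    fh.write(f"{cell}\t{gene}\t{t}\n")
    with open(out / "drug_targets.tsv", "w") as fh:
        for drug_id in bundle.library.drug_ids:
            rec = bundle.library.records[drug_id]
            for protein, score in sorted(rec.associations.items()):
                fh.write(f"{drug_id}\t{protein}\t{score!r}\n")
    with open(out / "fingerprints.tsv", "w") as fh:
        for drug_id in bundle.library.drug_ids:
            fp = bundle.library.fingerprint(drug_id)
            bits = ",".join(str(b) for b in sorted(fp.bits))
            fh.write(f"{drug_id}\t{fp.width}\t{bits}\n")
    with open(out / "modules.tsv", "w") as fh:
        for cell, module in sorted(bundle.modules.items()):
            fh.write(f"{cell}\t{','.join(sorted(module))}\n")
    write_synergy_table(bundle.originals, out / "synergy.tsv")

    files = sorted(p.name for p in out.glob("*.tsv"))
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "seed": bundle.config.seed,
        "checksums": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)


def load_dataset(in_dir: str | Path) -> SynthBundle:
    """Reconstruct a bundle from a written dataset directory."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    raw_cfg = manifest["config"]
    raw_cfg["targets_per_drug"] = tuple(raw_cfg["targets_per_drug"])
    cfg = SynthConfig(**raw_cfg)
    ppi = read_network(src / "edges.tsv", src / "nodes.tsv")
    go_table = GOEmbeddingTable.from_tsv(src / "go_embeddings.tsv")

    expression: dict[str, dict[str, int]] = {}
    for cell, gene, val in _rows(src / "expression.tsv", 3):
        expression.setdefault(cell, {})[gene] = int(val)
    cnv: dict[str, dict[str, str]] = {}
    for cell, gene, cat in _rows(src / "cnv.tsv", 3):
        cnv.setdefault(cell, {})[gene] = cat
    mutations: dict[str, dict[str, set[str]]] = {}
    for cell, gene, t in _rows(src / "mutations.tsv", 3):
        mutations.setdefault(cell, {}).setdefault(gene, set()).add(t)
    modules: dict[str, frozenset[str]] = {}
    for cell, members in _rows(src / "modules.tsv", 2):
        modules[cell] = frozenset(m for m in members.split(",") if m)

    cells = sorted(set(expression) | set(cnv) | set(mutations) | set(modules))
    profiles = {
        cell: CellLineProfile(
            cell_line_id=cell,
            expression=expression.get(cell, {}),
            cnv=cnv.get(cell, {}),
            mutations={g: frozenset(ts)
                       for g, ts in mutations.get(cell, {}).items()},
        )
        for cell in cells
    }

    associations: dict[str, dict[str, float]] = {}
    for drug_id, protein, score in _rows(src / "drug_targets.tsv", 3):
        associations.setdefault(drug_id, {})[protein] = float(score)
    fingerprints: dict[str, Fingerprint] = {}
    for drug_id, width, bits in _rows(src / "fingerprints.tsv", 3):
        bit_set = frozenset(
            int(b) for b in bits.split(",") if b
        )
        fingerprints[drug_id] = Fingerprint(bits=bit_set, width=int(width))
    records = {
        drug_id: DrugRecord(drug_id=drug_id, smiles=None,
                            associations=assoc)
        for drug_id, assoc in associations.items()
    }
    library = DrugLibrary(
        records=records, node_order=sorted(ppi.druggable),
        fingerprints=fingerprints,
    )

    originals = read_synergy_table(src / "synergy.tsv")
    return SynthBundle(
        config=cfg, ppi=ppi, profiles=profiles, go_table=go_table,
        library=library, originals=originals, modules=modules,
    )


def _rows(path: Path, n_cols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns"
                )
            yield tuple(parts)
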