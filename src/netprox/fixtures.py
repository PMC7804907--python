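"""Synthetic inputs with planted ground truth.

Every generator emits plain-text data files plus a YAML manifest recording
exactly what was planted (module members, drug targets, expected expressed
calls, affinity-filter survivors), so downstream checks compare against
construction-time truth rather than re-derived quantities.  All generators
are deterministic under their seed: the same plan yields byte-identical
files.

Fixture graphs default to the Barabasi-Albert preferential-attachment model
because degree-matched permutation behavior is only meaningfully exercised
on heavy-tailed degree distributions like a real interactome's.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .graphio import DrugTargetSet, GeneSet

EVIDENCE_CHOICES = ("structure3D", "Y2H", "kinase_substrate", "signaling", "literature")


def _gene(i: int) -> str:
    return f"G{i:04d}"


def _write_edges(g: nx.Graph, path: Path, rng: np.random.Generator) -> None:
    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges)
    labels = rng.choice(EVIDENCE_CHOICES, size=len(edges))
    with path.open("w") as fh:
        for (a, b), ev in zip(edges, labels):
            fh.write(f"{a}\t{b}\t{ev}\n")


def _write_manifest(manifest: dict, path: Path) -> None:
    path.write_text(yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False))


# -- graphs ------------------------------------------------------------------


def make_graph(plan: dict, out_dir) -> tuple[Path, dict]:
    """Generate a fixture interactome edge list plus its manifest.

    Plan keys: ``model`` (erdos_renyi | barabasi_albert | planted_module),
    ``n_nodes``, ``seed``, and per-model parameters (``p`` for Erdos-Renyi;
    ``m`` attachment edges for Barabasi-Albert; module/target parameters for
    planted_module, see :func:`_plant_module`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = plan.get("model", "barabasi_albert")
    n = int(plan["n_nodes"])
    seed = int(plan.get("seed", 0))
    rng = np.random.default_rng(seed)
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n, float(plan.get("p", 0.05)), seed=seed)
        manifest_extra = {}
    elif model == "barabasi_albert":
        m = int(plan.get("m", 3))
        if m >= n:
            raise ValueError(f"infeasible plan: attachment m={m} needs n_nodes > m")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
        manifest_extra = {}
    elif model == "planted_module":
        g, manifest_extra = _plant_module(plan, rng)
    else:
        raise ValueError(f"unknown graph model {model!r}")
    g = nx.relabel_nodes(g, {i: _gene(i) for i in g.nodes})
    manifest_extra = {
        k: ([_gene(i) for i in v] if isinstance(v, list) else v)
        for k, v in manifest_extra.items()
    }
    edge_path = out_dir / "edges.tsv"
    _write_edges(g, edge_path, rng)
    manifest = {
        "model": model,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "seed": seed,
        **manifest_extra,
    }
    _write_manifest(manifest, out_dir / "graph_manifest.yaml")
    return edge_path, manifest


def _plant_module(plan: dict, rng: np.random.Generator) -> tuple[nx.Graph, dict]:
    """Barabasi-Albert background with one planted connected module and a
    designated drug whose targets sit at the planted hop distance (1 = direct
    neighbors of the module)."""
    n = int(plan["n_nodes"])
    m = int(plan.get("m", 3))
    size = int(plan.get("module_size", 10))
    density = float(plan.get("module_internal_density", 0.6))
    n_targets = int(plan.get("n_targets", 5))
    if size > n or m >= n:
        raise ValueError("infeasible planted-module plan")
    g = nx.barabasi_albert_graph(n, m, seed=int(plan.get("seed", 0)))
    module = sorted(rng.choice(n, size=size, replace=False).tolist())
    # connect the module: random chain then extra internal edges up to density
    chain = list(module)
    rng.shuffle(chain)
    for a, b in zip(chain, chain[1:]):
        g.add_edge(a, b)
    possible = [(a, b) for i, a in enumerate(module) for b in module[i + 1 :]]
    want = int(round(density * len(possible)))
    have = sum(1 for a, b in possible if g.has_edge(a, b))
    candidates = [e for e in possible if not g.has_edge(*e)]
    if want > have and candidates:
        extra = rng.choice(len(candidates), size=min(want - have, len(candidates)), replace=False)
        for idx in sorted(extra.tolist()):
            g.add_edge(*candidates[idx])
    boundary = sorted(set().union(*(set(g.neighbors(v)) for v in module)) - set(module))
    if len(boundary) < n_targets:
        raise ValueError("infeasible plan: module boundary smaller than target count")
    targets = sorted(rng.choice(boundary, size=n_targets, replace=False).tolist())
    return g, {"module": list(module), "drug_targets": list(targets), "target_hop": 1}


def make_screen_fixture(
    out_dir,
    seed: int = 0,
    n_nodes: int = 300,
    n_drugs: int = 5,
    n_modules: int = 4,
    module_size: int = 12,
    n_targets: int = 6,
) -> dict:
    """Full screen fixture: graph, modules GMT, curated drug-target TSV.

    Plants exactly one proximal pair (DRUG0, MOD0): MOD0 is a connected
    cluster and DRUG0's targets are direct neighbors of it.  The remaining
    modules are random gene sets; the remaining drugs are planted negatives —
    their targets are drawn from nodes at shortest-path distance >= 2 from
    every module, so the fixture's ground truth covers the negatives as well
    as the positive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    edge_path, manifest = make_graph(
        {
            "model": "planted_module",
            "n_nodes": n_nodes,
            "m": 3,
            "module_size": module_size,
            "module_internal_density": 0.6,
            "n_targets": n_targets,
            "seed": seed,
        },
        out_dir,
    )
    g = nx.Graph()
    with edge_path.open() as fh:
        for line in fh:
            a, b, _ = line.rstrip("\n").split("\t")
            g.add_edge(a, b)
    planted_module = manifest["module"]
    planted_targets = manifest["drug_targets"]

    nodes = sorted(g.nodes)
    modules: dict[str, list[str]] = {"MOD0": planted_module}
    for i in range(1, n_modules):
        pool = sorted(set(nodes) - set(planted_module))
        modules[f"MOD{i}"] = sorted(rng.choice(pool, size=module_size, replace=False).tolist())

    # planted negatives: targets at distance >= 2 from every module gene
    near = set()
    for members in modules.values():
        for gene in members:
            near.add(gene)
            near.update(g.neighbors(gene))
    far_pool = sorted(set(nodes) - near)
    drugs: dict[str, list[str]] = {"DRUG0": planted_targets}
    for i in range(1, n_drugs):
        drugs[f"DRUG{i}"] = sorted(rng.choice(far_pool, size=n_targets, replace=False).tolist())

    gmt_path = out_dir / "modules.gmt"
    with gmt_path.open("w") as fh:
        for set_id in sorted(modules):
            fh.write("\t".join([set_id, f"fixture module {set_id}", *modules[set_id]]) + "\n")
    drug_path = out_dir / "drug_targets.tsv"
    with drug_path.open("w") as fh:
        fh.write("drug_id\ttarget_gene\n")
        for drug_id in sorted(drugs):
            for t in drugs[drug_id]:
                fh.write(f"{drug_id}\t{t}\n")

    full = {
        "seed": seed,
        "graph": str(edge_path),
        "modules_gmt": str(gmt_path),
        "drug_targets": str(drug_path),
        "planted_pair": ["DRUG0", "MOD0"],
        "modules": modules,
        "drugs": drugs,
    }
    _write_manifest(full, out_dir / "screen_manifest.yaml")
    return full


def screen_fixture_objects(manifest: dict) -> tuple[list[DrugTargetSet], list[GeneSet]]:
    """Materialize the drug/module objects recorded in a screen manifest."""
    drugs = [
        DrugTargetSet(d, frozenset(t)) for d, t in sorted(manifest["drugs"].items())
    ]
    sets = [
        GeneSet(s, f"fixture module {s}", frozenset(genes))
        for s, genes in sorted(manifest["modules"].items())
    ]
    return drugs, sets


# -- expression --------------------------------------------------------------


def make_expression(plan: dict, out_dir) -> tuple[Path, Path, dict]:
    """Generate an expression matrix (genes x samples), a sample->tissue map,
    and a manifest of planted truth.

    Plan keys: ``n_genes``, ``tissues`` (list; default includes "brain"),
    ``samples_per_tissue``, ``seed``, ``specific`` = {n_genes, tissue, fold}
    (tissue-specific genes with the stated fold elevation over a log-normal
    background), ``unexpressed`` = {n_genes, tissue} (genes planted below the
    CPM threshold in one tissue), and ``edge_case`` (bool: one gene with
    exactly 90% of one tissue's samples at/above threshold, which the strict
    "over 90%" rule must call unexpressed).

    The manifest records, per gene, the tissues in which it must be called
    expressed and, for specific genes, the tissue where its specificity
    z-score must be maximal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_genes = int(plan.get("n_genes", 100))
    tissues = list(plan.get("tissues", ["brain", "liver", "heart", "lung", "kidney"]))
    sper = int(plan.get("samples_per_tissue", 10))
    seed = int(plan.get("seed", 0))
    spec = dict(plan.get("specific", {"n_genes": 0, "tissue": "brain", "fold": 8.0}))
    unexp = dict(plan.get("unexpressed", {"n_genes": 0, "tissue": "liver"}))
    rng = np.random.default_rng(seed)

    genes = [_gene(i) for i in range(n_genes)]
    samples = [f"{t}_s{j:02d}" for t in tissues for j in range(sper)]
    tissue_of = {s: s.rsplit("_s", 1)[0] for s in samples}

    # background: clearly expressed everywhere (floor keeps calls unambiguous)
    values = 0.6 + rng.lognormal(mean=1.0, sigma=0.5, size=(n_genes, len(samples)))

    n_spec = int(spec.get("n_genes", 0))
    fold = float(spec.get("fold", 8.0))
    spec_tissue = spec.get("tissue", "brain")
    specific_genes = genes[:n_spec]
    col_idx = {s: k for k, s in enumerate(samples)}
    spec_cols = [col_idx[s] for s in samples if tissue_of[s] == spec_tissue]
    if n_spec:
        values[np.ix_(range(n_spec), spec_cols)] *= fold

    n_unexp = int(unexp.get("n_genes", 0))
    unexp_tissue = unexp.get("tissue", "liver")
    unexp_genes = genes[n_spec : n_spec + n_unexp]
    unexp_cols = [col_idx[s] for s in samples if tissue_of[s] == unexp_tissue]
    if n_unexp:
        values[np.ix_(range(n_spec, n_spec + n_unexp), unexp_cols)] = rng.uniform(
            0.0, 0.45, size=(n_unexp, len(unexp_cols))
        )

    edge_gene = None
    if plan.get("edge_case"):
        edge_gene = genes[-1]
        edge_tissue = tissues[0]
        edge_cols = [col_idx[s] for s in samples if tissue_of[s] == edge_tissue]
        row = np.full(len(edge_cols), 1.0)
        row[0] = 0.2  # one sample below threshold: fraction == 0.9, not over
        values[n_genes - 1, edge_cols] = row

    matrix_path = out_dir / "expression.tsv"
    with matrix_path.open("w") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for i, gene in enumerate(genes):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in values[i]) + "\n")
    map_path = out_dir / "tissue_map.tsv"
    with map_path.open("w") as fh:
        for s in samples:
            fh.write(f"{s}\t{tissue_of[s]}\n")

    expressed = {}
    for i, gene in enumerate(genes):
        exp_tissues = set(tissues)
        if gene in unexp_genes:
            exp_tissues.discard(unexp_tissue)
        if edge_gene is not None and gene == edge_gene:
            exp_tissues.discard(tissues[0])
        expressed[gene] = sorted(exp_tissues)
    manifest = {
        "seed": seed,
        "tissues": tissues,
        "samples_per_tissue": sper,
        "specific_genes": {g: spec_tissue for g in specific_genes},
        "fold": fold,
        "unexpressed_genes": {g: unexp_tissue for g in unexp_genes},
        "edge_case_gene": edge_gene,
        "expressed": expressed,
    }
    _write_manifest(manifest, out_dir / "expression_manifest.yaml")
    return matrix_path, map_path, manifest


# -- drug affinity table -----------------------------------------------------


def make_drug_table(plan: dict, out_dir) -> tuple[Path, dict]:
    """Generate an affinity TSV with a planted number of cutoff survivors.

    Plan keys: ``n_records``, ``n_pass`` (records at or below the 10 uM
    cutoff, including one exact-boundary row at 10,000 nM when
    ``boundary_rows`` is true, plus one just-failing row at 10,001 nM),
    ``seed``.  Every record is a distinct (drug, target) pair, so the
    survivor count equals the planted pass count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_records = int(plan.get("n_records", 50))
    n_pass = int(plan.get("n_pass", 23))
    boundary = bool(plan.get("boundary_rows", True))
    seed = int(plan.get("seed", 0))
    if n_records <= 0:
        raise ValueError("empty drug-table plan")
    if n_pass > n_records or (boundary and (n_pass < 1 or n_records - n_pass < 1)):
        raise ValueError("infeasible drug-table plan")
    rng = np.random.default_rng(seed)
    atypes = ["Ki", "Kd", "EC50", "IC50"]
    rows = []
    survivors = []
    for i in range(n_records):
        drug = f"D{i // 4:03d}"
        target = _gene(1000 + i)
        atype = atypes[i % 4]
        if i < n_pass:
            if boundary and i == 0:
                nm = 10_000.0
            else:
                nm = float(rng.uniform(1.0, 9_999.0))
            survivors.append((drug, target))
        else:
            if boundary and i == n_pass:
                nm = 10_001.0
            else:
                nm = float(rng.uniform(10_002.0, 1e6))
        # mix units to exercise normalization
        if i % 3 == 0:
            value, unit = nm / 1000.0, "uM"
        else:
            value, unit = nm, "nM"
        rows.append((drug, target, atype, value, unit, "human"))
    path = out_dir / "affinities.tsv"
    with path.open("w") as fh:
        fh.write("drug_id\ttarget_gene\taffinity_type\taffinity_value\taffinity_unit\tspecies\n")
        for drug, target, atype, value, unit, species in rows:
            fh.write(f"{drug}\t{target}\t{atype}\t{value:.6f}\t{unit}\t{species}\n")
    manifest = {
        "seed": seed,
        "n_records": n_records,
        "n_pass": n_pass,
        "survivors": [[d, t] for d, t in survivors],
    }
    _write_manifest(manifest, out_dir / "drug_table_manifest.yaml")
    return path, manifest


# -- bundle ------------------------------------------------------------------


def make_all(plan: dict, out_dir) -> dict:
    """Generate every fixture family named in a combined plan.

    The plan may contain ``graph``, ``screen``, ``expression`` and
    ``drug_table`` sections; each present section is generated into
    *out_dir*.  Returns the merged manifests.
    """
    out_dir = Path(out_dir)
    manifests: dict = {}
    if "graph" in plan:
        _, manifests["graph"] = make_graph(plan["graph"], out_dir)
    if "screen" in plan:
        manifests["screen"] = make_screen_fixture(out_dir, **plan["screen"])
    if "expression" in plan:
        _, _, manifests["expression"] = make_expression(plan["expression"], out_dir)
    if "drug_table" in plan:
        _, manifests["drug_table"] = make_drug_table(plan["drug_table"], out_dir)
    if not manifests:
        raise ValueError("plan names no fixture families (graph/screen/expression/drug_table)")
    return manifests
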