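"""End-to-end pipeline driver: per-condition stage chaining and comparison.

A "condition" is one stratum of the study (for example a sex x tissue
combination) with its own expression, trait, GWAS, eQTL, LD, pathway, and
network inputs.  Per condition the stages run as

    modules -> eigengenes -> trait filter -> MSEA (modules + pathways)
    -> supersets -> KDA -> subnetworks

and a cross-condition report classifies each superset as shared or
condition-specific using the same overlap-ratio + Fisher criterion as the
superset merging itself.  Every run writes its resolved configuration and a
log naming every threshold next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import coexpr, io, kda, msea, supersets
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All stage parameters with their defaults.

    The values mirror the analysis conventions: unsigned network power
    beta=6, static dissTOM cut, eigengene-trait filter at P < 1e-3, cis
    window +/-1 Mb with eQTL P < 1e-6, 10 chi quantile points over the top
    50%-99.9% with kappa=1, BH FDR < 0.05 at both MSEA and KDA, superset
    overlap ratio > 0.33, KDA neighborhood depth 1 and top-5 drivers.
    """

    method: str = "agglomerative"  # or "divisive"
    beta: float = 6.0
    cut_height: float = 0.99
    min_module_size: int = 20
    k_max: int = 4
    improvement_tol: float = 0.05
    sparsity: float = 0.05
    p_threshold: float = 1e-3
    cis_window: int = 1_000_000
    p_cut: float = 1e-6
    n_quantiles: int = 10
    top_range: tuple[float, float] = (0.50, 0.999)
    kappa: float = 1.0
    n_null: int = 1000
    msea_fdr: float = 0.05
    ratio_cut: float = 0.33
    merge_alpha: float = 0.05
    depth: int = 1
    min_neighborhood: int = 5
    kda_fdr: float = 0.05
    topk: int = 5

    def __post_init__(self):
        if self.method not in ("agglomerative", "divisive"):
            raise ConfigError(f"unknown clustering method {self.method!r}")


CONDITION_KEYS = {"expression", "trait", "gwas", "eqtl", "ld", "pathways",
                  "network"}


@dataclass
class PipelineConfig:
    conditions: dict[str, dict[str, object]]
    out_dir: str
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a pipeline YAML config; unknown keys reject."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"conditions", "out_dir", "seed", "params"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "conditions" not in raw or "out_dir" not in raw:
        raise ConfigError("config requires 'conditions' and 'out_dir'")
    param_names = {f.name for f in dataclasses.fields(PipelineParams)}
    extra = set(raw.get("params", {})) - param_names
    if extra:
        raise ConfigError(f"unknown parameter keys: {sorted(extra)}")
    params = dict(raw.get("params", {}))
    if "top_range" in params:
        params["top_range"] = tuple(params["top_range"])
    for name, cond in raw["conditions"].items():
        unknown = set(cond) - CONDITION_KEYS
        if unknown:
            raise ConfigError(f"condition {name!r}: unknown keys {sorted(unknown)}")
        missing = CONDITION_KEYS - set(cond)
        if missing:
            raise ConfigError(f"condition {name!r}: missing inputs {sorted(missing)}")
    return PipelineConfig(
        conditions=raw["conditions"], out_dir=str(raw["out_dir"]),
        seed=int(raw.get("seed", 0)), params=PipelineParams(**params))


def run_condition(
    data: Mapping[str, object],
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
    out: Path | None = None,
) -> dict[str, object]:
    """Run every stage for one condition on in-memory inputs.

    ``data`` carries expr (DataFrame), trait (Series), gwas, eqtl (DataFrames),
    ld (mapping), pathways (dict of sets), network (nx.Graph).  Returns the
    per-stage results; writes stage TSVs when ``out`` is given.
    """
    expr: pd.DataFrame = data["expr"]
    trait: pd.Series = data["trait"]

    # 1. module detection
    adj = coexpr.adjacency(expr, beta=params.beta)
    tom = coexpr.topological_overlap(adj)
    if params.method == "agglomerative":
        assignment = coexpr.cluster_agglomerative(
            tom, min_module_size=params.min_module_size,
            cut_height=params.cut_height)
    else:
        assignment = coexpr.cluster_divisive_kmedoids(
            tom, k_max=params.k_max, min_module_size=params.min_module_size,
            improvement_tol=params.improvement_tol, sparsity=params.sparsity)

    # 2. eigengenes + trait filter
    eigs = {m: coexpr.module_eigengene(expr, genes, m)
            for m, genes in assignment.modules.items()}
    tc = {m: coexpr.module_trait_correlation(e, trait, params.p_threshold)
          for m, e in eigs.items()}
    kept_modules = {m: assignment.modules[m] for m in tc if tc[m].passes}

    # 3. MSEA over trait-correlated modules plus pathways
    gene_sets = {**{f"module:{m}": g for m, g in kept_modules.items()},
                 **{f"pathway:{p}": g for p, g in data["pathways"].items()}}
    enr = msea.run_msea(
        gene_sets, data["gwas"], data["eqtl"], data["ld"],
        cis_window=params.cis_window, p_cut=params.p_cut,
        n_quantiles=params.n_quantiles, top_range=params.top_range,
        kappa=params.kappa, n_null=params.n_null, fdr_cut=params.msea_fdr,
        seed=seed)

    # 4. supersets of the significant sets
    sig = enr[enr["significant"]]["set_id"].tolist()
    universe = set(expr.index)
    for members in gene_sets.values():
        universe |= members
    merged = supersets.merge_pass(
        {s: gene_sets[s] for s in sig}, len(universe),
        ratio_cut=params.ratio_cut, alpha=params.merge_alpha) if sig else []

    # 5. KDA + subnetworks
    net = data["network"]
    ss_sets = supersets.supersets_to_gmt(merged)
    kda_table = None
    subnet = None
    if ss_sets and net is not None and net.number_of_nodes():
        try:
            kda_table = kda.run_kda(
                net, ss_sets, n_null=params.n_null, seed=seed,
                depth=params.depth, min_neighborhood=params.min_neighborhood,
                kappa=params.kappa, fdr_cut=params.kda_fdr, topk=params.topk)
            top = kda_table[kda_table["is_top"] & kda_table["is_key_driver"]]
            if len(top):
                subnet = kda.extract_subnetwork(
                    net, top["node"].tolist(), ss_sets)
        except DataError as exc:
            logger.warning("KDA skipped: %s", exc)

    result = {
        "assignment": assignment, "eigengenes": eigs, "trait_corr": tc,
        "kept_modules": kept_modules, "msea": enr, "supersets": merged,
        "kda": kda_table, "subnetwork": subnet,
    }
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        io.write_gmt(assignment.modules, out / "modules.gmt")
        eig_df = pd.DataFrame({m: e.values for m, e in eigs.items()})
        eig_df.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample")
        pd.DataFrame(
            [(m, t.r, t.p, t.passes) for m, t in tc.items()],
            columns=["module_id", "r", "p", "passes"],
        ).to_csv(out / "trait_correlation.tsv", sep="\t", index=False)
        enr.to_csv(out / "msea.tsv", sep="\t", index=False)
        io.write_gmt(ss_sets, out / "supersets.gmt")
        supersets.membership_table(merged).to_csv(
            out / "superset_members.tsv", sep="\t", index=False)
        if kda_table is not None:
            kda_table.to_csv(out / "kda.tsv", sep="\t", index=False)
        if subnet is not None:
            io.write_network_edges(sorted(subnet.graph.edges()),
                                   out / "subnetwork_edges.tsv")
            subnet.node_tags.to_csv(out / "subnetwork_nodes.tsv",
                                    sep="\t", index=False)
    return result


def compare_conditions(
    superset_tables: Mapping[str, Mapping[str, set[str]]],
    universe_size: int,
    ratio_cut: float = 0.33,
    alpha: float = 0.05,
    near_fdr: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Classify supersets as shared or condition-specific across conditions.

    A superset is shared with another condition when some superset there
    passes the same overlap-ratio + Bonferroni Fisher criterion used for
    merging (Bonferroni over all cross-condition pairs).  Returns one row
    per (condition, superset) with status and the matched partners.
    """
    if len(superset_tables) < 2:
        raise DataError("need at least 2 conditions to compare")
    conds = list(superset_tables)
    n_pairs = 0
    for a, b in combinations(conds, 2):
        n_pairs += len(superset_tables[a]) * len(superset_tables[b])
    threshold = alpha / n_pairs if n_pairs else alpha

    matches: dict[tuple[str, str], list[str]] = {
        (c, s): [] for c in conds for s in superset_tables[c]}
    for a, b in combinations(conds, 2):
        for sa, ga in superset_tables[a].items():
            for sb, gb in superset_tables[b].items():
                if not ga or not gb:
                    continue
                if supersets.overlap_ratio(set(ga), set(gb)) > ratio_cut and \
                        supersets.fisher_pair_p(set(ga), set(gb),
                                                universe_size) < threshold:
                    matches[(a, sa)].append(f"{b}:{sb}")
                    matches[(b, sb)].append(f"{a}:{sa}")
    rows = []
    for (cond, ss), partners in matches.items():
        status = "shared" if partners else "specific"
        fdr = (near_fdr or {}).get(cond, {}).get(ss, np.nan)
        near = bool(fdr < 0.10) if fdr == fdr else False
        rows.append((cond, ss, status, ";".join(sorted(partners)), near))
    return pd.DataFrame(rows, columns=[
        "condition", "superset_id", "status", "matched", "near_threshold"])


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all conditions from files and emit the cross-condition report.

    Any stage failure halts with the condition and stage named; outputs
    written before the failure are retained.
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    with open(out_root / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({
            "out_dir": config.out_dir, "seed": config.seed,
            "params": dataclasses.asdict(config.params),
            "conditions": config.conditions,
        }, fh, sort_keys=False)
    log_path = out_root / "run.log"
    with open(log_path, "w") as fh:
        fh.write("dimorphnet pipeline run\n")
        fh.write(f"seed\t{config.seed}\n")
        for f_ in dataclasses.fields(config.params):
            fh.write(f"{f_.name}\t{getattr(config.params, f_.name)}\n")
        fh.write("preservation_z_threshold\t2\n")

    results = {}
    for name, paths in config.conditions.items():
        cond_out = out_root / name
        stage = "load"
        try:
            nets = paths["network"]
            data = {
                "expr": io.read_expression(paths["expression"]),
                "trait": io.read_trait(paths["trait"]),
                "gwas": io.read_gwas(paths["gwas"]),
                "eqtl": io.read_eqtl(paths["eqtl"]),
                "ld": io.read_ld(paths["ld"]),
                "pathways": io.read_gmt(paths["pathways"]),
                "network": kda.union_network(
                    nets if isinstance(nets, (list, tuple)) else [nets]),
            }
            stage = "analysis"
            results[name] = run_condition(
                data, config.params, seed=config.seed, out=cond_out)
        except (OSError, DataError, ConfigError) as exc:
            raise DataError(
                f"condition {name!r} failed at stage {stage!r}: {exc}") from exc

    tables = {
        name: supersets.supersets_to_gmt(res["supersets"])
        for name, res in results.items()
    }
    universe: set[str] = set()
    for name, res in results.items():
        for ss in res["supersets"]:
            universe |= ss.genes
        universe |= set(results[name]["assignment"].unassigned)
        for genes in results[name]["assignment"].modules.values():
            universe |= genes
    if len(tables) >= 2:
        report = compare_conditions(tables, max(len(universe), 1))
        report.to_csv(out_root / "comparison.tsv", sep="\t", index=False)
    with open(out_root / "summary.json", "w") as fh:
        json.dump({
            name: {
                "n_modules": len(res["assignment"].modules),
                "n_trait_modules": len(res["kept_modules"]),
                "n_significant_sets": int(res["msea"]["significant"].sum()),
                "n_supersets": len(res["supersets"]),
                "n_key_drivers": int(res["kda"]["is_key_driver"].sum())
                if res["kda"] is not None else 0,
            } for name, res in results.items()
        }, fh, indent=2)
    return out_root
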