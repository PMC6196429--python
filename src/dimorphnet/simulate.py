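"""Synthetic cohort generator with recorded planted truth.

Emulates the data layers of a population-scale mouse panel study at desk
scale: a genes x samples expression matrix with block-correlated planted
coexpression modules, a quantitative trait driven by chosen module factors,
cis-eQTLs within a +/-1 Mb window of gene bodies, GWAS P-values that are
uniform under the null with planted low-P enrichment in the eSNPs of chosen
"causal" pathways, positional LD blocks, and a gene network containing
planted hub key drivers whose neighborhoods are enriched for disease genes.

Every planted entity is recorded in a :class:`PlantedTruth` object so each
downstream stage can be verified against a known answer.  All randomness
derives from ``SimConfig.seed``; the same config yields byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigError

# fixed per-operation stream tags so each generator op has an independent,
# reproducible substream of the master seed
_TAG_EXPR, _TAG_PATHWAYS, _TAG_GENETICS, _TAG_NETWORK = 11, 13, 17, 19


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the stated world: ~200 samples, a desk-scale genome of
    1500 genes and 20,000 SNPs, planted modules of 20-500 genes with
    within-module correlation 0.64, two trait-driving modules with a
    standardized effect of 0.5 each, three genetically "causal" pathways of
    50 genes whose eSNPs draw GWAS P from Beta(0.2, 1), and three planted
    network hubs of degree 40 with 70% disease-gene neighborhoods.
    """

    n_samples: int = 200
    n_genes: int = 1500
    n_snps: int = 20000
    module_sizes: tuple[int, ...] = (30, 50, 80, 100, 150)
    module_corr: float = 0.64
    trait_modules: tuple[int, ...] = (0, 1)
    trait_effect: float = 0.5
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (20, 100)
    enriched_pathways: tuple[int, ...] = (0, 1, 2)
    enriched_pathway_size: int = 50
    gwas_enrich_strength: float = 0.2
    eqtl_rate: float = 0.3
    max_esnps_per_gene: int = 3
    cis_window: int = 1_000_000
    ld_block_size: int = 10
    n_drivers: int = 3
    hub_degree: int = 40
    hub_disease_fraction: float = 0.7
    network_mean_degree: float = 3.0
    n_disease_genes: int = 60
    gene_spacing: int = 50_000
    gene_length: int = 10_000
    seed: int = 0
    # optional independent seed for the expression layer only: lets two
    # conditions share planted structure (modules, pathways, coordinates)
    # while drawing independent sampling noise
    expression_seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples, "n_genes": self.n_genes,
            "n_snps": self.n_snps, "n_pathways": self.n_pathways,
            "cis_window": self.cis_window, "ld_block_size": self.ld_block_size,
            "gene_spacing": self.gene_spacing, "gene_length": self.gene_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if any(s < 2 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module_sizes sum exceeds n_genes")
        if not 0 < self.module_corr < 1:
            raise ConfigError("module_corr must lie in (0, 1)")
        if any(m >= self.n_modules or m < 0 for m in self.trait_modules):
            raise ConfigError("trait_modules index out of range")
        if any(p >= self.n_pathways or p < 0 for p in self.enriched_pathways):
            raise ConfigError("enriched_pathways index out of range")
        if not 0 < self.gwas_enrich_strength <= 1:
            raise ConfigError("gwas_enrich_strength must lie in (0, 1]")
        if not 0 <= self.eqtl_rate <= 1:
            raise ConfigError("eqtl_rate must lie in [0, 1]")
        if self.hub_degree >= self.n_genes:
            raise ConfigError("hub_degree must be smaller than n_genes")
        if self.n_drivers < 0:
            raise ConfigError("n_drivers must be >= 0")


@dataclass
class PlantedTruth:
    """Record of everything the simulator buried, for downstream verification."""

    true_modules: dict[str, set[str]] = field(default_factory=dict)
    true_trait_modules: list[str] = field(default_factory=list)
    true_enriched_sets: list[str] = field(default_factory=list)
    true_drivers: list[str] = field(default_factory=list)
    disease_genes: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def gene_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def sample_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_samples))
    return [f"S{i:0{width}d}" for i in range(1, config.n_samples + 1)]


def gene_coordinates(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced gene bodies on a single synthetic chromosome (1-based)."""
    starts = np.arange(config.n_genes, dtype=np.int64) * config.gene_spacing + 1
    return pd.DataFrame({
        "gene": gene_ids(config),
        "start": starts,
        "end": starts + config.gene_length - 1,
    })


# ----------------------------------------------------------------- expression

def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Generate expression, trait, and the module part of the planted truth.

    Latent-factor model: genes of planted module *m* follow
    ``sqrt(rho) * f_m + sqrt(1 - rho) * noise`` with a shared per-sample
    factor ``f_m``, giving an expected within-module pairwise correlation of
    exactly ``rho``.  Background genes are independent standard normals.
    The trait is ``sum_m trait_effect * f_m + noise`` over the chosen trait
    modules, standardized.
    """
    if config.expression_seed is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.expression_seed, _TAG_EXPR]))
    else:
        rng = _rng(config, _TAG_EXPR)
    genes = gene_ids(config)
    samples = sample_ids(config)
    n, g = config.n_samples, config.n_genes

    values = rng.standard_normal((g, n))
    factors = rng.standard_normal((config.n_modules, n))
    rho = config.module_corr

    truth = PlantedTruth()
    offset = 0
    for m, size in enumerate(config.module_sizes):
        idx = slice(offset, offset + size)
        values[idx] = np.sqrt(rho) * factors[m] + np.sqrt(1 - rho) * values[idx]
        truth.true_modules[f"planted_{m + 1}"] = set(genes[offset:offset + size])
        offset += size

    trait = rng.standard_normal(n)
    for m in config.trait_modules:
        trait = trait + config.trait_effect * factors[m]
        truth.true_trait_modules.append(f"planted_{m + 1}")
    trait = (trait - trait.mean()) / trait.std()

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return expr, pd.Series(trait, index=samples, name="trait"), truth


# ------------------------------------------------------------------ pathways

def simulate_pathways(config: SimConfig) -> dict[str, set[str]]:
    """Random gene sets (GMT-style); enriched ones get a fixed size so the
    planted genetic signal is reproducible."""
    rng = _rng(config, _TAG_PATHWAYS)
    genes = np.array(gene_ids(config))
    lo, hi = config.pathway_size_range
    enriched = set(config.enriched_pathways)
    pathways: dict[str, set[str]] = {}
    for p in range(config.n_pathways):
        size = config.enriched_pathway_size if p in enriched \
            else int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"pathway_{p + 1}"] = set(members.tolist())
    return pathways


# ------------------------------------------------------------------ genetics

def simulate_genetics(
    config: SimConfig,
    pathways: Mapping[str, set[str]],
    truth: PlantedTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Generate GWAS summary statistics, a cis-eQTL table, and LD blocks.

    Genes in the enriched pathways are always given at least one cis-eSNP
    (so the planted signal is fully mapped); a further ``eqtl_rate`` fraction
    of the remaining genes receive eSNPs.  Every eSNP of an enriched-pathway
    gene draws its GWAS P from Beta(a, 1) with ``a = gwas_enrich_strength``;
    all other SNPs are Uniform(0, 1).  LD blocks are positional runs of
    ``ld_block_size`` consecutive SNPs.
    """
    rng = _rng(config, _TAG_GENETICS)
    if truth is None:
        truth = PlantedTruth()
    coords = gene_coordinates(config)
    universe = set(coords["gene"])
    for name, members in pathways.items():
        if not members <= universe:
            raise ConfigError(f"pathway {name!r} contains genes outside the universe")

    chrom_len = int(coords["end"].iloc[-1] + config.gene_spacing)
    snp_pos = np.sort(rng.choice(chrom_len, size=config.n_snps, replace=False)) + 1
    width = len(str(config.n_snps))
    snp_ids = np.array([f"rs{i:0{width}d}" for i in range(1, config.n_snps + 1)])

    # choose eQTL genes: enriched-pathway genes always, plus a random fraction
    enriched_names = [f"pathway_{p + 1}" for p in config.enriched_pathways]
    enriched_genes: set[str] = set()
    for name in enriched_names:
        enriched_genes |= pathways[name]
    others = [g for g in coords["gene"] if g not in enriched_genes]
    n_extra = int(round(config.eqtl_rate * len(others)))
    extra = rng.choice(np.array(others), size=n_extra, replace=False) if n_extra else []
    eqtl_genes = sorted(enriched_genes | set(extra))

    gene_row = coords.set_index("gene")
    rows = []
    for gene in eqtl_genes:
        start, end = int(gene_row.at[gene, "start"]), int(gene_row.at[gene, "end"])
        lo = np.searchsorted(snp_pos, start - config.cis_window, side="left")
        hi = np.searchsorted(snp_pos, end + config.cis_window, side="right")
        if hi <= lo:
            continue
        k = min(int(rng.integers(1, config.max_esnps_per_gene + 1)), hi - lo)
        chosen = rng.choice(np.arange(lo, hi), size=k, replace=False)
        for j in np.sort(chosen):
            rows.append((snp_ids[j], gene, 10.0 ** -rng.uniform(6.5, 12.0),
                         int(snp_pos[j]), start, end))
    eqtl = pd.DataFrame(rows, columns=io.EQTL_COLUMNS)

    # GWAS P-values: uniform null, Beta(a, 1) for eSNPs of enriched genes
    pvals = rng.uniform(0.0, 1.0, size=config.n_snps)
    mapped_enriched = eqtl[eqtl["gene"].isin(enriched_genes)]["snp"].unique()
    if len(mapped_enriched):
        idx = np.searchsorted(snp_ids, np.sort(mapped_enriched))
        pvals[idx] = rng.beta(config.gwas_enrich_strength, 1.0, size=len(idx))
    gwas = pd.DataFrame({
        "snp": snp_ids, "chrom": "chr1", "pos": snp_pos, "pvalue": pvals,
    })

    blocks = {sid: f"B{i // config.ld_block_size:05d}" for i, sid in enumerate(snp_ids)}

    truth.true_enriched_sets = list(enriched_names)
    for name in enriched_names:
        if eqtl[eqtl["gene"].isin(pathways[name])].empty:
            truth.warnings.append(f"enriched pathway {name} has no eQTL-mapped genes")
    return gwas, eqtl, blocks


# ------------------------------------------------------------------- network

def simulate_network(
    config: SimConfig,
    disease_genes: Iterable[str],
    truth: PlantedTruth | None = None,
):
    """Random background graph plus planted hub key drivers.

    Hubs are excluded from the background Erdos-Renyi layer so each hub's
    degree is exactly ``hub_degree``; a ``hub_disease_fraction`` share of its
    neighbors are disease genes.  Returns an undirected simple
    ``networkx.Graph`` and the truth record.
    """
    import networkx as nx

    rng = _rng(config, _TAG_NETWORK)
    if truth is None:
        truth = PlantedTruth()
    genes = gene_ids(config)
    universe = set(genes)
    disease = sorted(set(disease_genes))
    if not set(disease) <= universe:
        raise ConfigError("disease_genes not contained in the gene universe")
    if config.hub_degree >= config.n_genes:
        raise ConfigError("hub_degree must be smaller than n_genes")

    non_disease = [g for g in genes if g not in set(disease)]
    hubs = rng.choice(np.array(non_disease), size=config.n_drivers, replace=False) \
        if config.n_drivers else np.array([], dtype=object)
    hubs = sorted(hubs.tolist())
    hub_set = set(hubs)

    g = nx.Graph()
    g.add_nodes_from(genes)

    # background ER layer over non-hub nodes
    background = [x for x in genes if x not in hub_set]
    nb = len(background)
    n_pairs = nb * (nb - 1) // 2
    p_edge = min(config.network_mean_degree / max(nb - 1, 1), 1.0)
    m = rng.binomial(n_pairs, p_edge)
    pair_idx = rng.choice(n_pairs, size=m, replace=False)
    # map linear index -> (i, j) with i < j
    i = (np.floor((2 * nb - 1 - np.sqrt((2 * nb - 1) ** 2 - 8 * pair_idx)) / 2)).astype(np.int64)
    j = (pair_idx - i * (2 * nb - 1 - i) // 2 + i + 1).astype(np.int64)
    bg = np.array(background, dtype=object)
    g.add_edges_from(zip(bg[i], bg[j]))

    n_dis_nb = int(round(config.hub_disease_fraction * config.hub_degree))
    for hub in hubs:
        pool_dis = np.array([d for d in disease if d != hub], dtype=object)
        take_dis = min(n_dis_nb, len(pool_dis))
        chosen = list(rng.choice(pool_dis, size=take_dis, replace=False)) if take_dis else []
        pool_bg = np.array(
            [x for x in background if x not in set(disease) and x not in chosen],
            dtype=object)
        chosen += list(rng.choice(pool_bg, size=config.hub_degree - take_dis,
                                  replace=False))
        g.add_edges_from((hub, nb_gene) for nb_gene in chosen)

    truth.true_drivers = hubs
    truth.disease_genes = set(disease)
    return g, truth


# --------------------------------------------------------------------- truth

def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Write the planted truth as a human-readable TSV (kind, id, detail)."""
    rows: list[tuple[str, str, str]] = []
    for name, members in truth.true_modules.items():
        rows.append(("module", name, ",".join(sorted(members))))
    for name in truth.true_trait_modules:
        rows.append(("trait_module", name, ""))
    for name in truth.true_enriched_sets:
        rows.append(("enriched_set", name, ""))
    for gene in truth.true_drivers:
        rows.append(("driver", gene, ""))
    if truth.disease_genes:
        rows.append(("disease_genes", "disease", ",".join(sorted(truth.disease_genes))))
    for msg in truth.warnings:
        rows.append(("warning", "", msg))
    pd.DataFrame(rows, columns=["kind", "id", "detail"]).to_csv(
        path, sep="\t", index=False)


def read_truth(path: str | Path) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    truth = PlantedTruth()
    for _, row in df.iterrows():
        kind, name, detail = row["kind"], row["id"], row["detail"]
        if kind == "module":
            truth.true_modules[name] = set(detail.split(",")) if detail else set()
        elif kind == "trait_module":
            truth.true_trait_modules.append(name)
        elif kind == "enriched_set":
            truth.true_enriched_sets.append(name)
        elif kind == "driver":
            truth.true_drivers.append(name)
        elif kind == "disease_genes":
            truth.disease_genes = set(detail.split(",")) if detail else set()
        elif kind == "warning":
            truth.warnings.append(detail)
    return truth


# ------------------------------------------------------------------- cohorts

def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None):
    """Generate every layer of a synthetic cohort; optionally write all files.

    Returns a dict with keys expr, trait, pathways, gwas, eqtl, ld, network,
    truth.  Disease genes for the network layer are the genes of the first
    enriched pathway topped up with random genes to ``n_disease_genes``.
    """
    expr, trait, truth = simulate_expression(config)
    pathways = simulate_pathways(config)
    gwas, eqtl, ld = simulate_genetics(config, pathways, truth)

    rng = _rng(config, _TAG_NETWORK + 100)
    if config.enriched_pathways:
        disease = set(pathways[f"pathway_{config.enriched_pathways[0] + 1}"])
    else:
        disease = set()
    pool = np.array(sorted(set(gene_ids(config)) - disease))
    extra = max(config.n_disease_genes - len(disease), 0)
    if extra:
        disease |= set(rng.choice(pool, size=extra, replace=False).tolist())
    network, truth = simulate_network(config, disease, truth)

    result = {
        "expr": expr, "trait": trait, "pathways": pathways, "gwas": gwas,
        "eqtl": eqtl, "ld": ld, "network": network, "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_expression(expr, out / "expression.tsv")
        io.write_trait(trait, out / "trait.tsv")
        io.write_gmt(pathways, out / "pathways.gmt")
        io.write_gwas(gwas, out / "gwas.tsv")
        io.write_eqtl(eqtl, out / "eqtl.tsv")
        io.write_ld(ld, out / "ld.tsv")
        io.write_network_edges(sorted(network.edges()), out / "network.tsv")
        write_truth(truth, out / "truth.tsv")
        with open(out / "sim_config.txt", "w") as fh:
            for f_ in dataclasses.fields(config):
                fh.write(f"{f_.name}\t{getattr(config, f_.name)}\n")
    return result
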