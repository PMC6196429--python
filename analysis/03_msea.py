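#!/usr/bin/env python
"""Marker set enrichment of modules and pathways against the trait GWAS.

Gene sets (trait-correlated modules plus the pathway catalog) are mapped to
pruned cis-eSNPs and scored with the quantile chi statistic against 1000
size-matched random gene sets; BH FDR < 0.05 defines the enriched sets.
"""

from pathlib import Path

import pandas as pd

from dimorphnet import coexpr, io, msea

DATA = Path("scratch/analysis/data")
RESULTS = Path("results")
SEED = 1


def main() -> None:
    frames = []
    for cond in ("cond_A", "cond_B"):
        expr = io.read_expression(DATA / cond / "expression.tsv")
        trait = io.read_trait(DATA / cond / "trait.tsv")
        modules = io.read_gmt(DATA / cond / "modules.gmt")
        kept = {}
        for name, members in modules.items():
            eig = coexpr.module_eigengene(expr, members, name)
            if coexpr.module_trait_correlation(eig, trait).passes:
                kept[f"module:{name}"] = members
        pathways = {f"pathway:{k}": v
                    for k, v in io.read_gmt(DATA / cond / "pathways.gmt").items()}

        table = msea.run_msea(
            {**kept, **pathways},
            io.read_gwas(DATA / cond / "gwas.tsv"),
            io.read_eqtl(DATA / cond / "eqtl.tsv"),
            io.read_ld(DATA / cond / "ld.tsv"),
            n_null=1000, seed=SEED)
        table.insert(0, "condition", cond)
        frames.append(table)
        sig = table[table["significant"]]["set_id"].tolist()
        print(f"{cond}: {len(sig)} sets enriched at FDR<0.05: {sig}")

    pd.concat(frames).to_csv(RESULTS / "03_msea.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
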