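#!/usr/bin/env python
"""Merge the significantly enriched gene sets into non-redundant supersets.

Sets qualify for merging at overlap ratio > 0.33 plus Bonferroni-corrected
Fisher P < 0.05; connected components of qualifying pairs become the
supersets.  Same-annotation pairs that fail the quantitative criteria stay
separate and are reported.
"""

from pathlib import Path

import pandas as pd

from dimorphnet import io, supersets

DATA = Path("scratch/analysis/data")
RESULTS = Path("results")


def main() -> None:
    member_frames = []
    for cond in ("cond_A", "cond_B"):
        msea_table = pd.read_csv(RESULTS / "03_msea.tsv", sep="\t")
        msea_table = msea_table[msea_table["condition"] == cond]
        sig = set(msea_table[msea_table["significant"]]["set_id"])

        modules = {f"module:{k}": v
                   for k, v in io.read_gmt(DATA / cond / "modules.gmt").items()}
        pathways = {f"pathway:{k}": v
                    for k, v in io.read_gmt(DATA / cond / "pathways.gmt").items()}
        gene_sets = {**modules, **pathways}
        expr_genes = set(
            io.read_expression(DATA / cond / "expression.tsv").index)
        universe = expr_genes.union(*gene_sets.values())

        merged = supersets.merge_pass({s: gene_sets[s] for s in sig},
                                      len(universe))
        io.write_gmt(supersets.supersets_to_gmt(merged),
                     DATA / cond / "supersets.gmt")
        members = supersets.membership_table(merged)
        members.insert(0, "condition", cond)
        member_frames.append(members)
        print(f"{cond}: {len(sig)} enriched sets merged into "
              f"{len(merged)} supersets")
        for ss in merged:
            print(f"  {ss.superset_id}: {len(ss.genes)} genes "
                  f"<- {ss.member_set_ids}")

    pd.concat(member_frames).to_csv(RESULTS / "04_superset_members.tsv",
                                    sep="\t", index=False)


if __name__ == "__main__":
    main()
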