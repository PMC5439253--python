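"""Fisher-exact enrichment of each coexpression network against gene sets.

Builds a small GMT over the simulated gene namespace (one set per planted
module slice plus unrelated background sets), then tests each network's
gene list for over-representation with the one-sided Fisher exact test,
keeping terms with p < 0.05 and at least 3 member genes. The universe is
the set of genes surviving the zero-filter. Writes
results/enrichment_network<i>.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from comira.enrichment import (
    fisher_enrichment,
    filter_enriched,
    read_gmt,
    write_enrichment_table,
    write_gmt,
    GeneSetCollection,
)
from comira.expression import preprocess, read_expression_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    mrna = preprocess(read_expression_tsv(ROOT / "cohort" / "mrna_fpkm.tsv"))
    universe = set(mrna.gene_ids)

    truth = pd.read_csv(ROOT / "cohort" / "truth_modules.tsv", sep="\t")
    sets = {}
    for mod, grp in truth.groupby("module"):
        members = sorted(grp.gene_id)[:10]  # a slice, as a curated set would be
        sets[f"module{mod}_set"] = (f"planted module {mod} slice", frozenset(members))
    background = sorted(universe - set(truth.gene_id))
    for k in range(3):
        sets[f"background{k}_set"] = (
            f"unrelated background {k}",
            frozenset(background[20 * k: 20 * k + 12]),
        )
    gs = GeneSetCollection(sets, frozenset(universe))
    write_gmt(gs, ROOT / "toy_sets.gmt")

    networks = sorted(ROOT.glob("network*_genes.txt"))
    if not networks:
        print("run 04_coexpression_network.py first", file=sys.stderr)
        return 1
    for path in networks:
        name = path.stem.replace("_genes", "")
        query = {g.strip() for g in path.read_text().splitlines() if g.strip()}
        kept = filter_enriched(fisher_enrichment(query, gs), alpha=0.05, min_genes=3)
        out = ROOT / f"enrichment_{name}.tsv"
        write_enrichment_table(kept, out)
        print(f"{name} ({len(query)} genes): {len(kept)} enriched term(s)")
        for r in kept:
            print(f"  {r.term}\tcount={r.count}\t%={r.percent:.2f}\tp={r.p_value:.3g}")
    print("-> results/enrichment_network*.tsv (universe =", len(universe), "genes)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
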