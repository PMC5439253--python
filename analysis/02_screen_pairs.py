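"""Screen the simulated cohort for negatively correlated miRNA-mRNA pairs.

Reads the FPKM matrices written by 01_simulate_cohort.py, applies the
standard preprocessing (drop all-zero genes, log2 with 0.001 pseudocount),
computes the full mRNA x miRNA Pearson matrix, keeps pairs with r < -0.5,
and compares the hits against the planted ground truth. Writes
results/pairs.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from comira.correlation import cross_correlation_matrix, screen_negative_pairs, write_pair_table
from comira.expression import align_samples, preprocess, read_expression_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    mrna = preprocess(read_expression_tsv(ROOT / "cohort" / "mrna_fpkm.tsv"))
    mirna = preprocess(read_expression_tsv(ROOT / "cohort" / "mirna_fpkm.tsv"))
    mrna, mirna = align_samples(mrna, mirna)
    pairs = screen_negative_pairs(cross_correlation_matrix(mrna, mirna))
    write_pair_table(pairs, ROOT / "pairs.tsv")

    truth = pd.read_csv(ROOT / "cohort" / "truth_pairs.tsv", sep="\t")
    planted = set(zip(truth.mirna_id, truth.gene_id))
    found = {(p.mirna, p.gene) for p in pairs}
    print(f"screen: {len(pairs)} pair(s) with r < -0.5 "
          f"over {mrna.n_genes} x {mirna.n_genes} correlations")
    for p in pairs:
        tag = "planted" if (p.mirna, p.gene) in planted else "UNEXPECTED"
        print(f"  {p.mirna}\t{p.gene}\tr={p.r:.3f}\t[{tag}]")
    print(f"recovered {len(found & planted)}/{len(planted)} planted pairs, "
          f"{len(found - planted)} false positive(s) -> results/pairs.tsv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
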