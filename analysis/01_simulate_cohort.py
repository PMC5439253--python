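"""Generate the synthetic study cohort used by the downstream analyses.

Draws the default planted-structure cohort — 255 patients, 1,200 mRNAs,
60 miRNAs, five miRNA->target pairs at rho=-0.65, three coexpression
modules of 25/15/8 genes at rho_m=0.8, 2% all-zero genes — dichotomizes
the first planted miRNA at its median to define high/low expression
groups, draws the clinical table conditional on those groups, and writes
everything (plus the ground truth sidecars) under results/cohort/.
"""

import sys
from pathlib import Path

from comira.clinical import dichotomize_expression
from comira.expression import preprocess
from comira.simulate import SimulationConfig, generate_clinical, generate_expression, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20240901


def main() -> int:
    cfg = SimulationConfig(seed=SEED)
    mrna, mirna, truth = generate_expression(cfg)
    marker_id = truth.pairs[0]["mirna_id"]
    marker_log = preprocess(mirna).data.loc[marker_id]
    groups = dichotomize_expression(dict(marker_log))
    records = generate_clinical(cfg, groups)
    paths = write_cohort(OUT, mrna, mirna, truth, records, cfg)

    n_high = sum(1 for g in groups.values() if g == "high")
    print(f"cohort: {mrna.n_genes} mRNAs x {mirna.n_genes} miRNAs x {mrna.n_samples} patients")
    print(f"planted: {len(truth.pairs)} miRNA->target pairs, "
          f"{len(truth.module_members)} modules of sizes "
          f"{[len(m) for m in truth.module_members]}, "
          f"{len(truth.zero_genes)} all-zero genes")
    print(f"marker {marker_id}: {n_high} high / {len(groups) - n_high} low patients")
    print("written:", ", ".join(str(p.relative_to(OUT.parent.parent)) for p in paths.values()))
    return 0


if __name__ == "__main__":
    sys.exit(main())
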