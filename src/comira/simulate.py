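"""Synthetic paired mRNA/miRNA cohorts with known planted structure.

The generator emulates the shape of a tumor transcriptome cohort — paired
FPKM matrices over the same patients plus a categorical clinical table — at
a configurable scale, with three kinds of planted signal the pipeline is
meant to recover:

* **anti-correlated miRNA->target pairs**: a target gene's log expression is
  ``a - b * miRNA + noise`` with ``b`` and the noise variance chosen so the
  population Pearson correlation equals the requested rho < 0;
* **coexpression modules**: member genes load on a shared latent factor with
  loading sqrt(rho_m) and unit idiosyncratic variance, so every within-module
  pair has population correlation rho_m;
* **clinical effects**: binary features drawn with group-conditional
  probabilities (i.e., a configured odds ratio between high/low expression
  groups) and exponential survival with group-specific medians.

Everything is Gaussian on the log2 scale and then mapped to FPKM via
``2^x - pseudocount`` (clipped at 0) so the standard preprocessing path —
zero-filter, pseudocount, log2 — is exercised end to end. A configurable
fraction of all-zero genes is injected for the zero-filter to remove.
All randomness flows from a single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clinical import ClinicalRecord
from .expression import DEFAULT_PSEUDOCOUNT, ExpressionMatrix


class ConfigError(ValueError):
    pass


@dataclass
class PlantedPair:
    """One miRNA -> target gene regulation with target correlation rho < 0."""

    mirna_index: int
    gene_index: int
    rho: float


@dataclass
class Module:
    """A block of co-expressed genes with common pairwise correlation rho_m."""

    gene_indices: tuple[int, ...]
    rho_m: float


@dataclass
class ClinicalFeatureSpec:
    """Binary feature: P(category = yes) conditional on expression group."""

    p_high: float
    p_low: float
    missing_rate: float = 0.0


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the desk-scale study condition used throughout the
    test suite: 255 patients (the cohort size the pipeline is designed
    around), 1200 mRNAs x 60 miRNAs, five planted miRNA->target pairs at
    rho = -0.65, three coexpression modules of 25/15/8 genes at rho_m = 0.8,
    2% injected all-zero genes, and a small clinical battery with one truly
    associated feature (odds ratio 3), one null feature, and group-dependent
    survival. ``full_scale()`` gives the full cohort dimensions
    (17,300 x 612) with the same planted structure.
    """

    seed: int
    n_samples: int = 255
    n_mrna: int = 1200
    n_mirna: int = 60
    planted_pairs: list[PlantedPair] = field(
        default_factory=lambda: [PlantedPair(j, j, -0.65) for j in range(5)]
    )
    modules: list[Module] = field(
        default_factory=lambda: [
            Module(tuple(range(100, 125)), 0.8),
            Module(tuple(range(150, 165)), 0.8),
            Module(tuple(range(200, 208)), 0.8),
        ]
    )
    clinical_spec: dict[str, ClinicalFeatureSpec] = field(
        default_factory=lambda: {
            "polyps_history": ClinicalFeatureSpec(p_high=0.4, p_low=2 / 3, missing_rate=0.04),
            "distant_metastasis": ClinicalFeatureSpec(p_high=0.17, p_low=0.17, missing_rate=0.04),
        }
    )
    survival_median_days: dict[str, float] = field(
        default_factory=lambda: {"high": 200.0, "low": 500.0}
    )
    zero_gene_fraction: float = 0.02
    log_mean: float = 5.0
    log_mean_sd: float = 2.0
    log_sd: float = 1.0
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")
        for p in self.planted_pairs:
            if not (-1 < p.rho < 0):
                raise ConfigError(f"planted pair rho must be in (-1, 0), got {p.rho}")
            if not (0 <= p.mirna_index < self.n_mirna and 0 <= p.gene_index < self.n_mrna):
                raise ConfigError("planted pair index out of range")
        target_genes = {p.gene_index for p in self.planted_pairs}
        seen: set[int] = set()
        for m in self.modules:
            if not (0 < m.rho_m < 1):
                raise ConfigError(f"module rho_m must be in (0, 1), got {m.rho_m}")
            gi = set(m.gene_indices)
            if gi & target_genes or gi & seen:
                raise ConfigError("module gene sets must be disjoint from targets and each other")
            seen |= gi
        for name, spec in self.clinical_spec.items():
            for p in (spec.p_high, spec.p_low, spec.missing_rate):
                if not (0 <= p <= 1):
                    raise ConfigError(f"probability outside [0,1] in feature {name!r}")
        if not (0 <= self.zero_gene_fraction < 1):
            raise ConfigError("zero_gene_fraction must be in [0, 1)")

    @classmethod
    def full_scale(cls, seed: int) -> "SimulationConfig":
        """Cohort-scale dimensions: 17,300 mRNAs x 612 miRNAs x 255 samples."""
        return cls(seed=seed, n_mrna=17_300, n_mirna=612)


@dataclass
class SyntheticTruth:
    """Ground truth of one realized cohort, sufficient to score recovery."""

    pairs: list[dict]  # mirna_id, gene_id, target_rho, achieved_r
    module_members: list[list[str]]
    clinical_effects: dict[str, dict]
    zero_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs)


def _sample_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Draw one cohort: FPKM-scale mRNA and miRNA matrices plus ground truth.

    Identical (seed, config) inputs produce byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    n, G, M = cfg.n_samples, cfg.n_mrna, cfg.n_mirna
    samples = _sample_ids(n)
    mirna_ids = [f"sim-mir-{j:03d}" for j in range(M)]
    gene_ids = [f"GENE{i:05d}" for i in range(G)]

    mu_mir = rng.normal(cfg.log_mean, cfg.log_mean_sd, size=M)
    mirna_log = mu_mir[:, None] + rng.normal(0.0, cfg.log_sd, size=(M, n))

    mu_g = rng.normal(cfg.log_mean, cfg.log_mean_sd, size=G)
    mrna_log = mu_g[:, None] + rng.normal(0.0, cfg.log_sd, size=(G, n))

    # planted miRNA->target pairs: gene = a - b*miRNA + eps with
    # b / sqrt(b^2 + sigma_eps^2 / sigma_mir^2) = |rho|  (unit slope scale:
    # take b = |rho|, sigma_eps = sqrt(1 - rho^2) on standardized miRNA)
    pair_truth = []
    for p in cfg.planted_pairs:
        mir = mirna_log[p.mirna_index]
        mir_std = (mir - mir.mean()) / mir.std()
        eps = rng.normal(0.0, 1.0, size=n)
        target = mu_g[p.gene_index] + cfg.log_sd * (
            -abs(p.rho) * mir_std + np.sqrt(1 - p.rho**2) * eps
        )
        mrna_log[p.gene_index] = target
        achieved = float(np.corrcoef(mir, target)[0, 1])
        pair_truth.append(
            {
                "mirna_id": mirna_ids[p.mirna_index],
                "gene_id": gene_ids[p.gene_index],
                "target_rho": p.rho,
                "achieved_r": achieved,
            }
        )

    # modules: shared latent factor, loading sqrt(rho_m), unit idiosyncratic sd
    module_members = []
    for mod in cfg.modules:
        factor = rng.normal(0.0, 1.0, size=n)
        load = np.sqrt(mod.rho_m)
        resid_sd = np.sqrt(1.0 - mod.rho_m)
        for gi in mod.gene_indices:
            mrna_log[gi] = mu_g[gi] + cfg.log_sd * (
                load * factor + resid_sd * rng.normal(0.0, 1.0, size=n)
            )
        module_members.append([gene_ids[gi] for gi in mod.gene_indices])

    # inject all-zero genes among the unstructured ones
    structured = {p.gene_index for p in cfg.planted_pairs}
    for mod in cfg.modules:
        structured |= set(mod.gene_indices)
    free = np.array(sorted(set(range(G)) - structured), dtype=int)
    n_zero = min(int(round(cfg.zero_gene_fraction * G)), len(free))
    zero_idx = (
        rng.choice(free, size=n_zero, replace=False)
        if n_zero
        else np.array([], dtype=int)
    )

    mrna_fpkm = np.clip(2.0**mrna_log - cfg.pseudocount, 0.0, None)
    mirna_fpkm = np.clip(2.0**mirna_log - cfg.pseudocount, 0.0, None)
    mrna_fpkm[zero_idx] = 0.0

    truth = SyntheticTruth(
        pairs=pair_truth,
        module_members=module_members,
        clinical_effects={
            name: {
                "p_high": spec.p_high,
                "p_low": spec.p_low,
                "odds_ratio": (
                    (spec.p_high / (1 - spec.p_high)) / (spec.p_low / (1 - spec.p_low))
                    if 0 < spec.p_high < 1 and 0 < spec.p_low < 1
                    else float("nan")
                ),
            }
            for name, spec in cfg.clinical_spec.items()
        },
        zero_genes=[gene_ids[i] for i in sorted(zero_idx)],
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_fpkm, index=gene_ids, columns=samples), scale="fpkm"
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_fpkm, index=mirna_ids, columns=samples), scale="fpkm"
    )
    return mrna, mirna, truth


def generate_clinical(
    cfg: SimulationConfig, groups: dict[str, str]
) -> list[ClinicalRecord]:
    """Draw clinical records conditional on each patient's expression group.

    Binary features use the configured P(yes | group); survival is
    exponential with the configured per-group median (median = ln 2 / rate).
    Missing values are injected at each feature's configured rate.
    """
    rng = np.random.default_rng(
        int(np.random.SeedSequence([cfg.seed, 0x5EED]).generate_state(1)[0]) % (2**31)
    )
    patients = list(groups)
    if not patients:
        raise ConfigError("groups must cover at least one patient")
    records = []
    for pid in patients:
        grp = groups[pid]
        if grp not in ("high", "low"):
            raise ConfigError(f"unknown expression group {grp!r}")
        feats: dict[str, str | None] = {}
        for name, spec in cfg.clinical_spec.items():
            if rng.random() < spec.missing_rate:
                feats[name] = None
            else:
                p_yes = spec.p_high if grp == "high" else spec.p_low
                feats[name] = "yes" if rng.random() < p_yes else "no"
        median = cfg.survival_median_days[grp]
        surv = float(rng.exponential(median / np.log(2)))
        records.append(ClinicalRecord(pid, feats, surv))
    return records


def write_cohort(
    out_dir: str | Path,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    truth: SyntheticTruth,
    records: list[ClinicalRecord] | None = None,
    cfg: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the cohort in the TSV dialects the readers consume + truth sidecar."""
    from .expression import write_expression_tsv
    from .clinical import write_clinical_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": out / "mrna_fpkm.tsv",
        "mirna": out / "mirna_fpkm.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
        "truth_modules": out / "truth_modules.tsv",
    }
    write_expression_tsv(mrna, paths["mrna"])
    write_expression_tsv(mirna, paths["mirna"])
    truth.to_frame().to_csv(paths["truth_pairs"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"module": i + 1, "gene_id": g}
            for i, members in enumerate(truth.module_members)
            for g in members
        ]
    ).to_csv(paths["truth_modules"], sep="\t", index=False)
    if records is not None:
        paths["clinical"] = out / "clinical.tsv"
        write_clinical_tsv(records, paths["clinical"])
    if cfg is not None:
        paths["config"] = out / "sim_config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
    return paths
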