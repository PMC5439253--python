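"""Fisher-exact over-representation analysis against GMT gene sets.

For a query gene list (e.g., the members of a coexpression network) and each
gene set, a one-sided Fisher exact test asks whether the overlap is larger
than expected under hypergeometric sampling from the background universe.
A pathway is called enriched when p < alpha (strict) AND at least
``min_genes`` query genes belong to it. Raw p-values drive the filter, as is
conventional for this dual-filter style of pathway calling; a
Benjamini-Hochberg q column is reported for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe of testable genes."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise EnrichmentError(f"gene set {term!r} is empty")
        self.universe = frozenset(self.universe)


@dataclass
class EnrichmentResult:
    """Per-term Fisher result: overlap count, % of query, p, member genes."""

    term: str
    name: str
    count: int
    percent: float
    p_value: float
    genes: list[str]
    q_value: float = float("nan")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line, term id, description, member genes (tabs).

    Duplicate members within a line are stored once. Lines with fewer than 3
    fields raise a parse error naming the line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            term, name, *members = fields
            sets[term] = (name, frozenset(m for m in members if m))
    return GeneSetCollection(sets, frozenset(universe or ()))


def write_gmt(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (name, members) in gs.sets.items():
            fh.write("\t".join([term, name, *sorted(members)]) + "\n")


def fisher_enrichment(
    query: set[str], gs: GeneSetCollection, universe: set[str] | None = None
) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher exact test per gene set.

    The 2x2 table for a set S with universe U and query Q (all intersected
    with U) is [[|Q∩S|, |Q\\S|], [|S\\Q|, |U\\(Q∪S)|]]; p is the
    hypergeometric upper tail P(X >= |Q∩S|). Query genes outside the
    universe are dropped with a warning. Results sorted by ascending p, ties
    by term id.
    """
    uni = frozenset(universe) if universe is not None else gs.universe
    if not uni:
        raise EnrichmentError("empty universe")
    if not query:
        raise EnrichmentError("empty query gene list")
    q = frozenset(query) & uni
    dropped = len(query) - len(q)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the universe were dropped")
    if not q:
        raise EnrichmentError("no query genes remain inside the universe")
    if len(uni) <= len(q):
        raise EnrichmentError("universe must be larger than the query")
    M, N = len(uni), len(q)
    results = []
    for term, (name, members) in gs.sets.items():
        s = members & uni
        if not s:
            continue
        k = len(q & s)
        # hypergeometric upper tail: P(overlap >= k) drawing N from M with |s| successes
        p = float(stats.hypergeom.sf(k - 1, M, len(s), N))
        results.append(
            EnrichmentResult(
                term=term,
                name=name,
                count=k,
                percent=100.0 * k / N,
                p_value=min(p, 1.0),
                genes=sorted(q & s),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if results:
        ps = np.array([r.p_value for r in results])
        qvals = multipletests(ps, method="fdr_bh")[1]
        for r, qv in zip(results, qvals):
            r.q_value = float(qv)
    return results


def filter_enriched(
    results: list[EnrichmentResult], alpha: float = 0.05, min_genes: int = 3
) -> list[EnrichmentResult]:
    """Keep terms with p strictly below alpha and overlap count >= min_genes."""
    return [r for r in results if r.p_value < alpha and r.count >= min_genes]


def percent_of_network(count: int, network_size: int) -> float:
    """Overlap count as a percentage of the query network, 2-decimal rounding."""
    if network_size <= 0:
        raise EnrichmentError("network_size must be positive")
    if not (0 <= count <= network_size):
        raise EnrichmentError("count must be between 0 and network_size")
    return round(100.0 * count / network_size, 2)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results with columns Term, Count, %, p value, BH-q, Genes."""
    return pd.DataFrame(
        {
            "Term": [f"{r.term}: {r.name}" if r.name else r.term for r in results],
            "Count": [r.count for r in results],
            "%": [round(r.percent, 2) for r in results],
            "p value": [r.p_value for r in results],
            "BH-q": [r.q_value for r in results],
            "Genes": [", ".join(r.genes) for r in results],
        }
    )


def write_enrichment_table(results: list[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
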