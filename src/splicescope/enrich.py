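"""Gene-set over-representation and pairwise feature-dependency testing.

The enrichment test is a hypergeometric over-representation analysis (ORA)
of an unranked query gene list (typically the genes carrying significant
differential-splicing events) against gmt gene sets: with a universe of
``N`` genes, a set of effective size ``K``, a query of size ``n`` and an
overlap of ``k``, the p-value is the upper tail ``P(X >= k)`` of
``Hypergeometric(N, K, n)``.  Sets whose effective size (after intersection
with the universe) falls below ``min_size`` (default 20) are excluded.
P-values are Benjamini-Hochberg adjusted across the tested sets.

Feature dependency between two annotation classes is tested with a
two-sided Fisher exact test on the 2x2 presence/absence table over events;
the odds ratio is ``(a*d)/(b*c)`` with a Haldane correction of 0.5 added to
every cell iff any cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import ValidationError


class GmtError(ValueError):
    """Malformed gmt input; the message carries the line number."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    k: int  # overlap
    K: int  # effective set size
    n: int  # query size
    N: int  # universe size
    p: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValidationError(f"{self.name}: overlap k={self.k} outside [0, min(n, K)]")


@dataclass(frozen=True)
class DependencyResult:
    class_a: str
    class_b: str
    table: Tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p: float


def load_gmt(path: str) -> List[GeneSet]:
    """Read a gmt file (``name<TAB>description<TAB>gene...`` per line).

    Duplicate genes within a set collapse; an empty set or a repeated set
    name is an error.
    """
    sets: List[GeneSet] = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise GmtError(f"line {lineno}: gene set {name!r} has no genes")
            if name in names:
                raise GmtError(f"line {lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name=name, genes=frozenset(genes), source=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.genes)]) + "\n")


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(arr, method="fdr_bh")[1])


def ora_test(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    min_size: int = 20,
) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Set membership and the query are intersected with the universe before
    sizing; sets with effective size below ``min_size`` are not tested.
    Results are sorted by adjusted p, then name.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValidationError("universe must be non-empty")
    query_set = frozenset(query) & universe_set
    if not query_set:
        raise ValidationError("query must contain at least one universe gene")
    N, n = len(universe_set), len(query_set)
    tested: List[Tuple[str, int, int, float]] = []
    for gs in sets:
        eff = gs.genes & universe_set
        K = len(eff)
        if K < min_size:
            continue
        k = len(eff & query_set)
        # upper tail P(X >= k); sf(k-1) = P(X > k-1)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        tested.append((gs.name, k, K, min(p, 1.0)))
    adj = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(name=name, k=k, K=K, n=n, N=N, p=p, p_adj=pa)
        for (name, k, K, p), pa in zip(tested, adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.name))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": r.name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p": r.p, "p_adj": r.p_adj}
            for r in results
        ],
        columns=["name", "k", "K", "n", "N", "p", "p_adj"],
    )


class DegenerateTableError(ValueError):
    """The 2x2 dependency table has an all-zero margin."""


def feature_dependency_test(
    table: pd.DataFrame, class_a: str, class_b: str
) -> DependencyResult:
    """Fisher exact test of co-occurrence between two feature classes.

    ``table`` is the 23-column annotation table; a class is *present* for an
    event when its column (for DOMAIN/PTM: the protein-space column) is
    non-empty.  Cells: a = both present, b = a only, c = b only, d = neither.
    """
    for cls in (class_a, class_b):
        if cls not in table.columns:
            raise ValidationError(f"class {cls!r} not in annotation table")
    if len(table) == 0:
        raise DegenerateTableError("annotation table is empty")
    pa = table[class_a].fillna("").astype(str).str.len() > 0
    pb = table[class_b].fillna("").astype(str).str.len() > 0
    a = int((pa & pb).sum())
    b = int((pa & ~pb).sum())
    c = int((~pa & pb).sum())
    d = int((~pa & ~pb).sum())
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(
            f"degenerate 2x2 margin for {class_a} vs {class_b}: ({a},{b},{c},{d})"
        )
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    return DependencyResult(
        class_a=class_a, class_b=class_b, table=(a, b, c, d),
        odds_ratio=float(odds), p=float(p),
    )
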