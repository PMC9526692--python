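"""Over-representation analysis (ORA) of gene lists against annotation sets.

A generic hypergeometric upper-tail test replacing external web enrichment
services: with background size N, annotation-set size K, query-list size n
and overlap k, the p-value is P(X >= k) for X ~ Hypergeom(N, K, n) and the
enrichment ratio is (k/n) / (K/N). Annotation sets are supplied as GMT
files, keeping the analysis hermetic (no database downloads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (e.g. a GO category) and its member genes."""

    term_id: str
    name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k: int  # overlap with the query list
    n: int  # query-list size
    K: int  # set size within the background
    N: int  # background size
    ratio: float  # (k/n) / (K/N)
    p_value: float  # hypergeometric upper tail P(X >= k)


def ora(
    genes: Iterable[str],
    sets: Sequence[AnnotationSet],
    background: Iterable[str],
    alpha: float | None = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test of ``genes`` against ``sets``.

    Set members are intersected with the background before testing; query
    genes absent from the background are an error. Results are filtered at
    ``alpha`` (pass ``None`` to keep all) and sorted by p-value, ties broken
    by term id. With ``bh_correct`` the filter applies to Benjamini-Hochberg
    adjusted p-values (the reported p stays raw).
    """
    bg = set(background)
    query = set(genes)
    offenders = sorted(query - bg)
    if offenders:
        raise ValueError(f"query genes absent from background: {offenders}")
    if not sets:
        raise ValueError("no annotation sets supplied")
    N, n = len(bg), len(query)
    results = []
    for s in sets:
        members = s.genes & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        ratio = (k / n) / (K / N) if n else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(s.term_id, s.name, k, n, K, N, ratio, min(p, 1.0))
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if alpha is not None:
        if bh_correct:
            adjusted = stats.false_discovery_control(
                [r.p_value for r in results], method="bh"
            )
            results = [r for r, q in zip(results, adjusted) if q < alpha]
        else:
            results = [r for r in results if r.p_value < alpha]
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term_id,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "ratio": r.ratio,
                "p": r.p_value,
            }
            for r in results
        ]
    )


def split_lists(records) -> dict[str, list[str]]:
    """Partition classified significant genes into the four regulation lists.

    down_T8 = down_T8_only + down_both, up_T8 = up_T8_only + up_both, and
    analogously at T28; a gene regulated at both times appears in two lists.
    """
    lists: dict[str, list[str]] = {
        "down_T8": [],
        "up_T8": [],
        "down_T28": [],
        "up_T28": [],
    }
    for rec in records:
        cat = rec.category
        if cat in ("down_T8_only", "down_both"):
            lists["down_T8"].append(rec.gene)
        if cat in ("up_T8_only", "up_both"):
            lists["up_T8"].append(rec.gene)
        if cat in ("down_T28_only", "down_both"):
            lists["down_T28"].append(rec.gene)
        if cat in ("up_T28_only", "up_both"):
            lists["up_T28"].append(rec.gene)
    return lists
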