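"""Gene-set over-representation analysis (ORA).

Hypergeometric upper-tail test of a gene list against a reference
background for each term of a term->genes map, with Benjamini-Hochberg
FDR control, plus accounting of population-private significant terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermResult:
    term: str
    description: str
    k: int  # list genes in term
    K: int  # reference genes in term
    n: int  # list size
    N: int  # reference size
    p: float
    q: float = float("nan")


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    pvals = list(pvalues)
    if not pvals:
        return []
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(x) for x in q]


def overrepresentation_test(
    gene_list,
    reference_list,
    term_map: dict[str, set[str] | list[str]],
    descriptions: dict[str, str] | None = None,
    min_term_size: int = 5,
    max_term_size: int = 2000,
) -> list[TermResult]:
    """Hypergeometric ORA of ``gene_list`` against ``reference_list``.

    Term gene sets are intersected with the reference before testing;
    terms with no reference gene, or outside the size bounds, are
    skipped.  List genes missing from the reference are logged and
    dropped.  Results carry BH-FDR q-values and are sorted by p.
    """
    reference = set(reference_list)
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    stray = genes - reference
    if stray:
        log.warning("%d gene(s) absent from the reference dropped from the list",
                    len(stray))
        genes &= reference
        if not genes:
            raise ValueError("no list gene is in the reference")
    N, n = len(reference), len(genes)
    descriptions = descriptions or {}

    results = []
    for term, members in term_map.items():
        in_ref = set(members) & reference
        K = len(in_ref)
        if K == 0 or not (min_term_size <= K <= max_term_size):
            continue
        k = len(in_ref & genes)
        p = hypergeometric_tail(k, N, K, n)
        results.append(TermResult(term, descriptions.get(term, ""), k, K, n, N, p))
    qvals = bh_fdr([r.p for r in results])
    results = [
        TermResult(r.term, r.description, r.k, r.K, r.n, r.N, r.p, q)
        for r, q in zip(results, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def significant_terms(results: list[TermResult], fdr: float = 0.05) -> set[str]:
    return {r.term for r in results if r.q < fdr}


def private_term_analysis(
    per_population: dict[str, set[str]],
    category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Population-private significant terms and optional category tallies.

    A term is private to a population when it is significant there and in
    no other population.  Returns a frame indexed by population with
    columns n_significant, n_private, private_terms, plus per-category
    private counts when a term->category map is supplied.
    """
    if len(per_population) < 2:
        raise ValueError("need >= 2 populations")
    rows = {}
    for pop, terms in per_population.items():
        others = set().union(*(t for p, t in per_population.items() if p != pop))
        private = terms - others
        row = {
            "n_significant": len(terms),
            "n_private": len(private),
            "private_terms": ";".join(sorted(private)),
        }
        if category_map:
            cats: dict[str, int] = {}
            for t in private:
                cats[category_map.get(t, "Other")] = cats.get(category_map.get(t, "Other"), 0) + 1
            for cat, count in sorted(cats.items()):
                row[f"private_{cat}"] = count
        rows[pop] = row
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0)


def results_to_frame(results: list[TermResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "description": r.description, "k": r.k, "K": r.K,
             "n": r.n, "N": r.N, "p": r.p, "q": r.q}
            for r in results
        ],
        columns=["term", "description", "k", "K", "n", "N", "p", "q"],
    )
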