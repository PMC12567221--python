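"""Over-representation analysis (ORA) against user-supplied term–gene collections.

Generic hypergeometric enrichment standing in for GO/KEGG analyses: given a
query gene set, an annotation collection (GMT) and a universe, each term with
at least one overlapping gene gets the exact hypergeometric upper-tail
probability P(X >= k), Benjamini–Hochberg adjusted within its category
(BP/CC/MF/pathway) by default.  Term counts from live databases are
version-dependent and are deliberately not reproduced here; the statistics
are.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "pathway")

__all__ = [
    "Term",
    "AnnotationCollection",
    "EnrichmentResult",
    "hypergeom_p",
    "bh_adjust",
    "ora",
    "top_terms",
    "results_to_frame",
]


@dataclass
class Term:
    term_id: str
    name: str
    category: str
    genes: set[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass
class AnnotationCollection:
    """term_id -> Term mapping with GMT round-trip."""

    terms: dict[str, Term] = field(default_factory=dict)

    def add(self, term: Term) -> None:
        self.terms[term.term_id] = term

    def universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out

    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for tid in sorted(self.terms):
            t = self.terms[tid]
            genes = "\t".join(sorted(t.genes))
            lines.append(f"{tid}\t{t.category}|{t.name}\t{genes}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path, default_category: str = "pathway") -> "AnnotationCollection":
        coll = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            tid, desc, genes = parts[0], parts[1], parts[2:]
            if "|" in desc:
                cat, name = desc.split("|", 1)
                cat = cat if cat in CATEGORIES else default_category
                name = name if cat in CATEGORIES else desc
            else:
                cat, name = default_category, desc
            coll.add(Term(term_id=tid, name=name, category=cat, genes={g for g in genes if g}))
        return coll


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    category: str
    k: int  # overlap size
    K: int  # term size (within universe)
    n: int  # query size (within universe)
    N: int  # universe size
    p: float
    p_adj: float = 1.0
    significant: bool = False
    overlap: tuple[str, ...] = ()


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing n genes from a universe of N containing K term members, the
    probability of observing k or more members in the draw.
    """
    if min(k, K, n, N) < 0 or K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, aligned to input order."""
    ps = list(pvals)
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p!r}")
    if not ps:
        return []
    return list(multipletests(ps, method="fdr_bh")[1])


def ora(
    query: Iterable[str],
    annotations: AnnotationCollection,
    universe: Iterable[str] | None = None,
    p_threshold: float = 0.05,
    adjust_within_category: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``query`` against every term with overlap >= 1.

    ``universe`` defaults to the union of all annotation genes.  Query symbols
    outside the universe are dropped with a logged warning.  BH adjustment is
    applied within each category (global with
    ``adjust_within_category=False``); results are sorted by ascending p,
    ties broken by term id, and flagged significant at raw p < p_threshold.
    """
    uni = set(universe) if universe is not None else annotations.universe()
    if not uni:
        raise ValueError("enrichment universe is empty")
    q_all = set(query)
    q = q_all & uni
    if len(q) < len(q_all):
        logger.warning(
            "dropped %d query symbols outside the universe", len(q_all) - len(q)
        )
    results: list[EnrichmentResult] = []
    for tid in sorted(annotations.terms):
        term = annotations.terms[tid]
        genes = term.genes & uni
        overlap = q & genes
        if not overlap or not genes:
            continue
        p = hypergeom_p(len(overlap), len(genes), len(q), len(uni))
        results.append(
            EnrichmentResult(
                term_id=tid,
                name=term.name,
                category=term.category,
                k=len(overlap),
                K=len(genes),
                n=len(q),
                N=len(uni),
                p=p,
                overlap=tuple(sorted(overlap)),
            )
        )
    group_key = (lambda r: r.category) if adjust_within_category else (lambda r: "all")
    by_group: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_group.setdefault(group_key(r), []).append(r)
    for group in by_group.values():
        adj = bh_adjust([r.p for r in group])
        for r, a in zip(group, adj):
            r.p_adj = float(a)
            r.significant = r.p < p_threshold
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def top_terms(
    results: Sequence[EnrichmentResult],
    per_category: int = 10,
    exclude: Sequence[str] = (),
) -> list[EnrichmentResult]:
    """Up to ``per_category`` lowest-p terms per category after name exclusions.

    ``exclude`` holds regular-expression patterns matched case-insensitively
    against term names (e.g. disease pathways deemed unrelated to the study
    context); matching terms are removed before ranking.
    """
    patterns = [re.compile(p, re.IGNORECASE) for p in exclude]
    kept = [r for r in results if not any(p.search(r.name) for p in patterns)]
    out: list[EnrichmentResult] = []
    for cat in CATEGORIES:
        cat_results = sorted(
            (r for r in kept if r.category == cat), key=lambda r: (r.p, r.term_id)
        )
        out.extend(cat_results[:per_category])
    return out


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "category": r.category,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )
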