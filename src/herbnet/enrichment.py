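"""Overrepresentation analysis (ORA) with BH-FDR control.

A query gene set (typically the hub targets surviving the topological
screen) is tested against an annotation collection with the one-sided
hypergeometric test; p-values are adjusted by Benjamini-Hochberg step-up
within each annotation category (BP / CC / MF / pathway separately, the
usual behaviour of GO tools), and results are ranked by FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ValidationError

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"term {self.term_id!r} has an empty member set")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"term {self.term_id!r} has unknown category {self.category!r}"
            )


@dataclass
class GeneSetCollection:
    """An ordered list of annotation terms with unique identifiers."""

    terms: list[GeneSetTerm]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate term ids in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.members
        return out


@dataclass
class EnrichmentRow:
    """One term's overrepresentation record.

    ``k`` of the ``n`` query genes fall in the term, which covers ``K`` of
    the ``N`` universe genes.  ``overlap`` is the actual intersection and
    ``members`` the term's (universe-restricted) member set, kept so that
    pathway networks can be built from ranked rows.
    """

    term_id: str
    name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float
    rank: int
    overlap: frozenset[str]
    members: frozenset[str]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The survival function is evaluated in log space by scipy, so extreme
    tails remain accurate.  ``k = 0`` returns exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValidationError(f"K and n cannot exceed N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValidationError(f"k={k} exceeds min(K, n)=min({K}, {n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    include_zero: bool = False,
    adjust_within_category: bool = True,
) -> list[EnrichmentRow]:
    """Hypergeometric overrepresentation of ``query`` in every term.

    Parameters
    ----------
    query
        Gene set to test; must be contained in the universe.
    collection
        Annotation terms.  Members are intersected with the universe
        before testing, and terms emptied by that restriction are dropped.
    universe
        Background gene set.  Defaults to the union of all term members.
    include_zero
        Report terms with zero query overlap (p = 1) as well.  They are
        always counted in the multiple-testing burden either way.
    adjust_within_category
        Run BH separately per category (default) or globally.

    Returns rows ranked by (fdr, p, term_id); ``rank`` is 1-based.
    """
    universe_set = set(universe) if universe is not None else collection.all_genes()
    query_set = set(query)
    if not universe_set:
        raise InputError("empty universe")
    if not query_set:
        raise InputError("empty query gene set")
    if not query_set <= universe_set:
        missing = sorted(query_set - universe_set)[:5]
        raise InputError(f"query genes outside the universe, e.g. {missing}")

    N = len(universe_set)
    n = len(query_set)
    tested = []
    for term in collection:
        members = frozenset(term.members & universe_set)
        if not members:
            continue
        overlap = frozenset(members & query_set)
        p = hypergeom_upper_tail(len(overlap), len(members), n, N)
        tested.append((term, members, overlap, p))

    if not tested:
        return []

    pvals = np.array([p for *_, p in tested])
    fdr = np.empty_like(pvals)
    if adjust_within_category:
        cats = np.array([t.category for t, *_ in tested])
        for c in np.unique(cats):
            mask = cats == c
            fdr[mask] = bh_adjust(pvals[mask])
    else:
        fdr[:] = bh_adjust(pvals)

    rows = [
        EnrichmentRow(
            term_id=term.term_id,
            name=term.name,
            category=term.category,
            k=len(overlap),
            K=len(members),
            n=n,
            N=N,
            p_value=p,
            fdr=float(q),
            rank=0,
            overlap=overlap,
            members=members,
        )
        for (term, members, overlap, p), q in zip(tested, fdr)
    ]
    if not include_zero:
        rows = [r for r in rows if r.k >= 1]
    rows.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def top_terms(
    rows: Sequence[EnrichmentRow], top_n: int = 20, fdr_cutoff: float = 0.05
) -> list[EnrichmentRow]:
    """First ``top_n`` ranked rows passing the (strict) FDR cutoff."""
    passing = [r for r in rows if r.fdr < fdr_cutoff]
    return list(passing[:top_n])
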