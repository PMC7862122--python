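"""Compound-target set algebra.

Merges per-compound target predictions from multiple sources into
deduplicated per-compound sets and their union, and intersects the union
with a disease gene list.  Identifiers live in the gene-symbol namespace
(uppercased); an optional synonym table maps aliases onto canonical
symbols without any network lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError


def _resolve_synonyms(synonym_table: Mapping[str, str]) -> dict[str, str]:
    """Collapse alias chains (A -> B -> C becomes A -> C); reject cycles."""
    table = {k.strip().upper(): v.strip().upper() for k, v in synonym_table.items()}
    resolved: dict[str, str] = {}
    for start in table:
        seen = [start]
        cur = start
        while cur in table:
            cur = table[cur]
            if cur in seen:
                raise ValidationError(f"synonym cycle detected: {' -> '.join(seen + [cur])}")
            seen.append(cur)
        resolved[start] = cur
    return resolved


def normalize_ids(
    raw_ids: Iterable[str], synonym_table: Mapping[str, str] | None = None
) -> list[str]:
    """Trim, uppercase, alias-map and deduplicate gene identifiers.

    Empty strings are dropped; output keeps the order of first occurrence.
    Alias chains in the synonym table are resolved to their terminal
    symbol, so the operation is idempotent.
    """
    mapping = _resolve_synonyms(synonym_table) if synonym_table else {}
    out: list[str] = []
    seen: set[str] = set()
    for raw in raw_ids:
        sym = str(raw).strip().upper()
        if not sym:
            continue
        sym = mapping.get(sym, sym)
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def union_compound_targets(
    associations: pd.DataFrame,
) -> tuple[dict[str, set[str]], list[str], dict[str, int]]:
    """Per-compound target sets, their sorted union, and per-compound counts.

    Associations are deduplicated on (compound, target): the same hit
    reported by several prediction sources counts once.
    """
    per_compound: dict[str, set[str]] = {}
    for cid, group in associations.groupby("compound_id", sort=False):
        per_compound[cid] = set(group["target_id"])
    union = sorted(set().union(*per_compound.values())) if per_compound else []
    counts = {cid: len(s) for cid, s in per_compound.items()}
    return per_compound, union, counts


@dataclass(frozen=True)
class VennSummary:
    """Counts and membership of the compound-target / disease intersection."""

    n_compound_targets: int
    n_disease_genes: int
    n_overlap: int
    overlap: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "n_compound_targets": self.n_compound_targets,
            "n_disease_genes": self.n_disease_genes,
            "n_overlap": self.n_overlap,
            "overlap": sorted(self.overlap),
        }


def intersect_with_disease(
    compound_targets: Iterable[str], disease_genes: Iterable[str]
) -> VennSummary:
    """Exact set intersection of the target union with the disease list."""
    targets = set(compound_targets)
    disease = set(disease_genes)
    overlap = frozenset(targets & disease)
    return VennSummary(len(targets), len(disease), len(overlap), overlap)


def per_compound_key_counts(
    associations: pd.DataFrame, key_targets: Iterable[str]
) -> dict[str, int]:
    """How many of the key (hub) targets each compound is linked to."""
    keys = set(key_targets)
    per_compound, _, _ = union_compound_targets(associations)
    return {cid: len(s & keys) for cid, s in per_compound.items()}
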