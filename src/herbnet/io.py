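"""Readers and writers for the pipeline's plain-text artifact formats.

Everything is TSV, GMT, newline-delimited gene lists, or JSON; all writers
emit deterministic (sorted or input-ordered) output so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .config import GroundTruth
from .enrichment import EnrichmentRow, GeneSetCollection, GeneSetTerm
from .errors import InputError


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_compounds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str})
    for col in ("id", "ob", "dl"):
        if col not in df.columns:
            raise InputError(f"{path}: compound table needs column {col!r}")
    return df


def read_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("compound_id", "target_id"):
        if col not in df.columns:
            raise InputError(f"{path}: association table needs column {col!r}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df


def read_gene_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in genes))
    return path


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV (with or without a header line) or SIF edge file."""
    g = nx.Graph()
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) == 3:  # SIF: source relation target
            u, _, v = parts
        elif len(parts) == 2:
            u, v = parts
            if (u, v) == ("source", "target"):
                continue
        elif len(parts) == 1:  # isolated node (SIF convention)
            g.add_node(parts[0])
            continue
        else:
            raise InputError(f"{path}: cannot parse edge line {ln!r}")
        if u != v:
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    covered = {x for e in edges for x in e}
    with path.open("w") as fh:
        fh.write("source\ttarget\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    isolated = sorted(set(g.nodes()) - covered)
    if isolated:
        side = path.with_suffix(path.suffix + ".isolated.txt")
        write_gene_list(isolated, side)
    return path


def read_gmt(path: str | Path, categories: str | Path | None = None) -> GeneSetCollection:
    """Standard GMT (term, description, members...) plus an optional
    ``term_id -> category`` sidecar TSV; terms default to ``pathway``."""
    cat_map: dict[str, str] = {}
    if categories is not None:
        cats = pd.read_csv(categories, sep="\t", dtype=str)
        cat_map = dict(zip(cats["term_id"], cats["category"]))
    terms = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}: GMT line with no members: {ln!r}")
        tid, desc, members = parts[0], parts[1], parts[2:]
        terms.append(GeneSetTerm(tid, desc, cat_map.get(tid, "pathway"), frozenset(members)))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> tuple[Path, Path]:
    """Write GMT plus the category sidecar ``<stem>.categories.tsv``."""
    path = Path(path)
    with path.open("w") as fh:
        for t in collection:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")
    sidecar = path.with_suffix(".categories.tsv")
    pd.DataFrame(
        {"term_id": [t.term_id for t in collection], "category": [t.category for t in collection]}
    ).to_csv(sidecar, sep="\t", index=False)
    return path, sidecar


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    for col in ("sample_id", "group", "gene", "ct"):
        if col not in df.columns:
            raise InputError(f"{path}: Ct table needs column {col!r}")
    return df


def read_affinity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ligand_id": str, "receptor_id": str})
    for col in ("ligand_id", "receptor_id", "score"):
        if col not in df.columns:
            raise InputError(f"{path}: affinity table needs column {col!r}")
    return df


def enrichment_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
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
                "p_value": r.p_value,
                "fdr": r.fdr,
                "rank": r.rank,
                "overlap_genes": ",".join(sorted(r.overlap)),
            }
            for r in rows
        ]
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
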