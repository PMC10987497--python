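"""Connectome partner ranking from neuPrint-style connection tables.

Works on the flat connection-export dialect (one row per pre-body →
post-body connection with a synapse-count weight, as exported from the
hemibrain dataset): aggregate by cell type, rank the upstream or
downstream partners of a type with a weight threshold, and emit the
node/link structure consumed by Sankey renderers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["bodyId_pre", "type_pre", "bodyId_post", "type_post", "weight"]
UNTYPED = "untyped"


class ConnectomeError(ValueError):
    """Raised for malformed connection tables or unknown cell types."""


@dataclass
class SynapseTable:
    """Typed synaptic connections; duplicate body pairs are summed on load."""

    df: pd.DataFrame  # canonical columns, one row per (pre body, post body)

    @property
    def total_weight(self) -> int:
        return int(self.df["weight"].sum())

    @property
    def n_connections(self) -> int:
        return len(self.df)

    def known_types(self) -> list[str]:
        return sorted(set(self.df["type_pre"]) | set(self.df["type_post"]))


@dataclass
class RankingEntry:
    partner_type: str
    total_weight: int
    n_partner_bodies: int


@dataclass
class PartnerRanking:
    """Type-level partner ranking of one source type, one direction.

    Entries are sorted by descending total weight, ties broken
    lexicographically by partner type. ``dropped_weight`` is the summed
    weight of partners removed by the threshold, so that
    retained + dropped equals the source-incident total.
    """

    source_type: str
    direction: str  # downstream | upstream
    entries: list[RankingEntry]
    min_weight: int
    dropped_weight: int

    @property
    def retained_weight(self) -> int:
        return sum(e.total_weight for e in self.entries)


@dataclass
class SankeyData:
    """Node labels + indexed links, serializable for Sankey renderers."""

    nodes: list[str]
    links: list[tuple[int, int, int]]  # (source idx, target idx, value)

    def to_json_dict(self) -> dict:
        return {
            "nodes": [{"label": n} for n in self.nodes],
            "links": [
                {"source": s, "target": t, "value": v} for s, t, v in self.links
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")


def from_dataframe(df: pd.DataFrame) -> SynapseTable:
    """Canonicalize a raw connection table (sum duplicates, fill types)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConnectomeError(
            f"missing required columns {missing}; found {list(df.columns)}"
        )
    df = df[REQUIRED_COLUMNS].copy()
    for col in ("type_pre", "type_post"):
        df[col] = df[col].astype(object)
        blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
        df.loc[blank, col] = UNTYPED
        df[col] = df[col].astype(str)
    weights = pd.to_numeric(df["weight"], errors="raise")
    if (weights < 1).any() or not np.allclose(weights, np.round(weights)):
        raise ConnectomeError("weights must be integers >= 1")
    df["weight"] = weights.astype(np.int64)
    out = (
        df.groupby(["bodyId_pre", "type_pre", "bodyId_post", "type_post"], as_index=False)[
            "weight"
        ]
        .sum()
        .sort_values(["bodyId_pre", "bodyId_post"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SynapseTable(df=out)


def load_synapse_table(path: str | Path) -> SynapseTable:
    """Read a delimited neuPrint connection export (CSV/TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return from_dataframe(df)


def dump_synapse_table(table: SynapseTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.df.to_csv(path, sep=sep, index=False)


def rank_partners(
    table: SynapseTable,
    source_type: str,
    direction: str = "downstream",
    min_weight: int = 1,
) -> PartnerRanking:
    """Rank the typed partners of ``source_type`` by summed synapse weight.

    ``downstream`` sums weights of rows whose *pre* type is the source
    (partners are post types); ``upstream`` the converse. Partners whose
    total weight falls below ``min_weight`` are dropped but their weight is
    accounted in ``dropped_weight``.
    """
    if direction not in ("downstream", "upstream"):
        raise ConnectomeError(f"direction must be downstream/upstream, got {direction!r}")
    if source_type not in table.known_types():
        raise ConnectomeError(
            f"unknown source type {source_type!r}; known types: {table.known_types()}"
        )
    src_col, partner_type_col, partner_body_col = (
        ("type_pre", "type_post", "bodyId_post")
        if direction == "downstream"
        else ("type_post", "type_pre", "bodyId_pre")
    )
    sub = table.df[table.df[src_col] == source_type]
    grouped = sub.groupby(partner_type_col).agg(
        total_weight=("weight", "sum"),
        n_partner_bodies=(partner_body_col, "nunique"),
    )
    entries = [
        RankingEntry(str(t), int(row["total_weight"]), int(row["n_partner_bodies"]))
        for t, row in grouped.iterrows()
    ]
    entries.sort(key=lambda e: (-e.total_weight, e.partner_type))
    kept = [e for e in entries if e.total_weight >= min_weight]
    dropped = sum(e.total_weight for e in entries if e.total_weight < min_weight)
    return PartnerRanking(
        source_type=source_type,
        direction=direction,
        entries=kept,
        min_weight=min_weight,
        dropped_weight=int(dropped),
    )


def to_sankey(ranking: PartnerRanking) -> SankeyData:
    """One source node + one node per retained partner; link value = weight.

    Downstream rankings link source → partner; upstream link partner →
    source. The summed link values equal the retained ranking weight.
    """
    nodes = [ranking.source_type] + [e.partner_type for e in ranking.entries]
    links = []
    for i, e in enumerate(ranking.entries, start=1):
        if ranking.direction == "downstream":
            links.append((0, i, e.total_weight))
        else:
            links.append((i, 0, e.total_weight))
    return SankeyData(nodes=nodes, links=links)
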