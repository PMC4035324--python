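"""Functional-category aggregation of DEG lists.

Given a user-supplied gene -> categories mapping (COG letters, pathway
subgroups, or any other vocabulary), tally up- and down-regulated DEGs per
category for a transition.  A gene annotated with k categories contributes
once to each of them (multi-counting across categories, single-counting
within); DEGs absent from the mapping are tallied under ``unannotated``.
Sparse categories can be dropped with a minimum-total filter applied across
all transitions together (default threshold 4).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError

UNANNOTATED = "unannotated"
DEFAULT_MIN_TOTAL = 4


class CategoryMap:
    """gene_id -> list of category labels."""

    def __init__(self, mapping: Mapping[str, Sequence[str]]):
        self._map: dict[str, list[str]] = {}
        for gene, cats in mapping.items():
            labels = [str(c) for c in cats]
            if any(not c for c in labels):
                raise InputError(f"gene {gene!r} has an empty category label")
            self._map[gene] = labels

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __getitem__(self, gene: str) -> list[str]:
        return self._map[gene]

    def get(self, gene: str, default=None):
        return self._map.get(gene, default)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryMap":
        """Two-column TSV (gene, category); repeated genes accumulate."""
        mapping: dict[str, list[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.rstrip("\n").startswith("gene"):
                raise InputError(f"{path}: expected a header starting with 'gene'")
            for line in fh:
                gene, category = line.rstrip("\n").split("\t")
                mapping.setdefault(gene, [])
                if category not in mapping[gene]:
                    mapping[gene].append(category)
        return cls(mapping)


def aggregate(
    records: pd.DataFrame,
    cmap: CategoryMap,
    include_empty: bool = False,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-category (n_up, n_down) table for one transition's DEGs.

    ``records`` is a screen table (rows with ``is_deg == False`` are
    ignored if the column is present).  With ``include_empty`` and an
    explicit category vocabulary, zero rows are kept.
    """
    transitions = set(records["transition"].unique()) if len(records) else set()
    if len(transitions) > 1:
        raise InputError(f"records mix transitions: {sorted(transitions)}")
    degs = records[records["is_deg"]] if "is_deg" in records.columns else records

    tallies: dict[str, dict[str, int]] = {}
    if include_empty and categories is not None:
        for c in categories:
            tallies[c] = {"n_up": 0, "n_down": 0}
    for gene_id, row in degs.iterrows():
        cats = cmap.get(gene_id)
        labels = sorted(set(cats)) if cats else [UNANNOTATED]
        col = "n_up" if row["direction"] == "up" else "n_down"
        for c in labels:
            tallies.setdefault(c, {"n_up": 0, "n_down": 0})[col] += 1

    df = pd.DataFrame.from_dict(tallies, orient="index").rename_axis("category")
    if df.empty:
        df = pd.DataFrame(columns=["n_up", "n_down"]).rename_axis("category")
    df = df.astype(int)
    df["n_total"] = df["n_up"] + df["n_down"]
    return df.sort_index()


def filter_categories(
    tables: Sequence[pd.DataFrame],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> list[pd.DataFrame]:
    """Drop categories whose DEG total across all transitions is < min_total.

    Mirrors the convention of excluding pathway subgroups with fewer than a
    handful of DEGs summed over every stage transition.  ``unannotated`` is
    never dropped.
    """
    if not tables:
        return []
    totals: dict[str, int] = {}
    for t in tables:
        for cat, row in t.iterrows():
            totals[cat] = totals.get(cat, 0) + int(row["n_total"])
    keep = {c for c, n in totals.items() if n >= min_total or c == UNANNOTATED}
    return [t[t.index.isin(keep)] for t in tables]
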