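"""Expressed-gene sets per stage and their 4-way Venn partition.

A gene is "expressed" in a stage when its unambiguous tag count reaches a
threshold (default 1, shared with the quantification module so expressed-set
accounting and DEG accounting cannot diverge).  The Venn partition tabulates
all 15 non-empty membership patterns over the four stages, and percentages
are reported both against the genome (catalog size) and against the union of
expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import pandas as pd

from .errors import InputError
from .quantify import ExpressionProfile

N_STAGES = 4


def expressed_set(profile: ExpressionProfile, min_count: int = 1) -> set[str]:
    """Genes with unambiguous count >= min_count in this library."""
    if min_count < 1:
        raise InputError("min_count must be >= 1")
    return set(profile.expressed(min_count))


def _pattern_label(pattern: tuple[bool, ...], labels: Sequence[str]) -> str:
    return "+".join(l for l, m in zip(labels, pattern) if m)


@dataclass
class VennPartition:
    """Region counts of a 4-set Venn diagram over stages."""

    labels: tuple[str, ...]
    region_counts: dict[tuple[bool, ...], int]
    genome_size: int

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    @property
    def stage_totals(self) -> dict[str, int]:
        totals = {}
        for i, label in enumerate(self.labels):
            totals[label] = sum(
                n for pat, n in self.region_counts.items() if pat[i]
            )
        return totals

    def count(self, *stages: str) -> int:
        """Count of the region for genes expressed in exactly these stages."""
        pattern = tuple(l in stages for l in self.labels)
        if not any(pattern):
            raise InputError("at least one stage required")
        unknown = set(stages) - set(self.labels)
        if unknown:
            raise InputError(f"unknown stages: {sorted(unknown)}")
        return self.region_counts.get(pattern, 0)


def venn_partition(
    sets: Sequence[set[str]],
    genome_size: int,
    labels: Sequence[str] | None = None,
) -> VennPartition:
    """Partition four expressed-gene sets into the 15 Venn regions."""
    if len(sets) != N_STAGES:
        raise InputError(f"exactly {N_STAGES} gene sets required, got {len(sets)}")
    labels = tuple(labels) if labels is not None else ("S1", "S2", "S3", "S4")
    if len(labels) != N_STAGES:
        raise InputError("labels must match the number of sets")
    union = set().union(*sets)
    if genome_size < len(union):
        raise InputError("genome_size smaller than the union of expressed genes")
    region_counts: dict[tuple[bool, ...], int] = {
        pat: 0
        for pat in product((False, True), repeat=N_STAGES)
        if any(pat)
    }
    for gene in union:
        pattern = tuple(gene in s for s in sets)
        region_counts[pattern] += 1
    return VennPartition(labels=labels, region_counts=region_counts, genome_size=genome_size)


def percentages(part: VennPartition) -> pd.DataFrame:
    """Region and stage-total percentages of genome and of expressed genes.

    Ratios are stored at full precision; round only when rendering (the
    conventional display is one decimal).
    """
    if part.genome_size <= 0 or part.union_size <= 0:
        raise InputError("genome and union sizes must be positive")
    rows = []
    for pattern in sorted(part.region_counts, reverse=True):
        n = part.region_counts[pattern]
        rows.append(
            {
                "region": _pattern_label(pattern, part.labels),
                "kind": "region",
                "n": n,
                "pct_genome": 100.0 * n / part.genome_size,
                "pct_expressed": 100.0 * n / part.union_size,
            }
        )
    for label, n in part.stage_totals.items():
        rows.append(
            {
                "region": label,
                "kind": "stage_total",
                "n": n,
                "pct_genome": 100.0 * n / part.genome_size,
                "pct_expressed": 100.0 * n / part.union_size,
            }
        )
    rows.append(
        {
            "region": "any",
            "kind": "union",
            "n": part.union_size,
            "pct_genome": 100.0 * part.union_size / part.genome_size,
            "pct_expressed": 100.0,
        }
    )
    return pd.DataFrame(rows, columns=["region", "kind", "n", "pct_genome", "pct_expressed"])
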