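"""Tag-to-gene quantification and sequencing-depth saturation.

Clean tags are assigned to genes through the reference index with best-hit
semantics and at most one mismatch:

1. exact match to a unique reference tag -> counted for that gene;
2. exact match to an ambiguous reference tag -> excluded;
3. otherwise, all reference tags at Hamming distance 1 over the 17-bp
   variable region are collected (the CATG anchor must match exactly); if
   they belong to exactly one gene the tag is counted for it, if to several
   it is excluded as ambiguous;
4. otherwise the tag is unmapped.

Gene expression is the number of unambiguously assigned tags, normalized to
transcripts per million clean tags: tpm = count * 1e6 / total_clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cleaning import TagCountTable
from .errors import InputError
from .reference import ANCHOR, TAG_LENGTH, TagIndex

_BASES = "ACGT"


@dataclass
class MappingTallies:
    """Per-distinct-observed-tag assignment outcomes."""

    exact_unique: int = 0
    mm1_unique: int = 0
    ambiguous_excluded: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.exact_unique + self.mm1_unique + self.ambiguous_excluded + self.unmapped

    def as_dict(self) -> dict:
        return {
            "exact_unique": self.exact_unique,
            "mm1_unique": self.mm1_unique,
            "ambiguous_excluded": self.ambiguous_excluded,
            "unmapped": self.unmapped,
        }


@dataclass
class ExpressionProfile:
    """Per-gene unambiguous tag counts and TPM for one stage library."""

    library_id: str
    counts: pd.Series  # gene -> unambiguous tag count (int)
    total_clean: int
    tallies: MappingTallies = field(default_factory=MappingTallies)

    @property
    def tpm(self) -> pd.Series:
        return self.counts * 1e6 / self.total_clean

    def expressed(self, min_count: int = 1) -> pd.Index:
        if min_count < 1:
            raise InputError("min_count must be >= 1")
        return self.counts.index[self.counts >= min_count]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"count": self.counts, "tpm": self.tpm})
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def _mm1_variants(tag: str):
    """All 51 single-substitution variants of the 17-bp variable region."""
    for i in range(len(ANCHOR), TAG_LENGTH):
        orig = tag[i]
        for b in _BASES:
            if b != orig:
                yield tag[:i] + b + tag[i + 1 :]


def assign_tag(tag: str, index: TagIndex) -> tuple[str | None, str]:
    """Assign one observed 21-mer to (gene_id or None, category).

    Category is one of ``exact_unique``, ``mm1_unique``,
    ``ambiguous_excluded``, ``unmapped``.
    """
    if len(tag) != TAG_LENGTH:
        raise InputError(f"observed tag {tag!r} is not {TAG_LENGTH} bp")
    genes = index.tag_to_genes.get(tag)
    if genes is not None:
        if len(genes) == 1:
            return genes[0], "exact_unique"
        return None, "ambiguous_excluded"
    hit_genes: set[str] = set()
    for variant in _mm1_variants(tag):
        owners = index.tag_to_genes.get(variant)
        if owners:
            hit_genes.update(owners)
            if len(hit_genes) > 1:
                return None, "ambiguous_excluded"
    if len(hit_genes) == 1:
        return next(iter(hit_genes)), "mm1_unique"
    return None, "unmapped"


def map_tags(
    table: TagCountTable,
    index: TagIndex,
    gene_universe: Sequence[str] | None = None,
) -> ExpressionProfile:
    """Map a clean-tag count table to a per-gene expression profile.

    The gene universe defaults to all genes carrying a reference tag; genes
    never observed get count 0.  The TPM denominator is the library's total
    clean tags, not the assigned subset.
    """
    if len(index) == 0:
        raise InputError("empty tag index")
    universe = list(gene_universe) if gene_universe is not None else index.gene_ids
    gene_counts = dict.fromkeys(universe, 0)
    tallies = MappingTallies()
    for tag, count in table.counts.items():
        gene, category = assign_tag(tag, index)
        setattr(tallies, category, getattr(tallies, category) + 1)
        if gene is not None:
            if gene not in gene_counts:
                gene_counts[gene] = 0
                universe.append(gene)
            gene_counts[gene] += count
    counts = pd.Series(gene_counts, dtype=np.int64)
    return ExpressionProfile(
        library_id=table.library_id,
        counts=counts,
        total_clean=table.total_clean,
        tallies=tallies,
    )


@dataclass
class SaturationCurve:
    """Detected-gene count as a function of subsampled tag depth."""

    library_id: str
    depths: np.ndarray
    genes_detected: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "genes_detected": self.genes_detected}
        )

    def plot(self, ax=None):
        """Line plot of genes detected vs depth (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.depths, self.genes_detected, marker="o")
        ax.set_xlabel("tags sampled")
        ax.set_ylabel("genes detected")
        ax.set_title(f"saturation: {self.library_id}")
        return ax


def saturation(
    table: TagCountTable,
    index: TagIndex,
    depths: Sequence[int],
    seed: int,
) -> SaturationCurve:
    """Subsample the library without replacement and count detected genes.

    For each depth, that many tag observations are drawn (nested prefixes of
    one seeded permutation, so the curve is non-decreasing by construction),
    mapped through the index, and the number of genes with at least one
    assigned tag recorded.
    """
    total = table.total_clean
    depths_arr = np.asarray(sorted(int(d) for d in depths), dtype=np.int64)
    if len(depths_arr) == 0:
        raise InputError("depths must be non-empty")
    if depths_arr[0] < 0 or depths_arr[-1] > total:
        raise InputError(f"depths must lie in [0, total_clean={total}]")

    tags = list(table.counts)
    counts = np.fromiter((table.counts[t] for t in tags), dtype=np.int64, count=len(tags))
    # gene assignment per distinct tag is depth-independent
    gene_of_tag = np.full(len(tags), -1, dtype=np.int64)
    gene_ids: dict[str, int] = {}
    for i, tag in enumerate(tags):
        gene, _cat = assign_tag(tag, index)
        if gene is not None:
            gene_of_tag[i] = gene_ids.setdefault(gene, len(gene_ids))

    observations = np.repeat(np.arange(len(tags)), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(observations)

    detected = np.zeros(len(depths_arr), dtype=np.int64)
    for k, depth in enumerate(depths_arr):
        genes = gene_of_tag[observations[:depth]]
        detected[k] = len(np.unique(genes[genes >= 0]))
    return SaturationCurve(
        library_id=table.library_id, depths=depths_arr, genes_detected=detected
    )


def merge_profiles(profiles: Sequence[ExpressionProfile]) -> pd.DataFrame:
    """Merge per-stage profiles into one genes x stages count matrix."""
    if not profiles:
        raise InputError("no profiles to merge")
    df = pd.DataFrame({p.library_id: p.counts for p in profiles}).fillna(0).astype(np.int64)
    df.index.name = "gene_id"
    return df
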