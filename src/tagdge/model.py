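"""Model/results interface over the DEG screen and stage-set accounting.

:class:`DGEModel` wraps a genes x stages matrix of unambiguous tag counts
plus the per-library clean-tag totals; :meth:`DGEModel.fit` runs the exact
two-library count test over every successive stage transition and returns a
:class:`DGEResults` carrying the per-gene test tables, the declared DEG
sets, transition summaries, the expressed-set Venn partition, and a text
``summary()``.

Example
-------
>>> model = DGEModel.from_profiles([bu, eg, el, ma], genome_size=11534)
>>> res = model.fit()          # FDR <= 0.001, |log2FC| >= 1
>>> res.summary()
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryMap, aggregate
from .degs import (
    DEFAULT_FDR,
    DEFAULT_MIN_LOG2FC,
    TransitionSummary,
    screen,
    summarize_transition,
)
from .errors import InputError
from .quantify import ExpressionProfile, merge_profiles
from .stagesets import VennPartition, percentages, venn_partition


class DGEModel:
    """Four-stage tag digital-gene-expression model.

    Parameters
    ----------
    counts
        DataFrame of unambiguous tag counts, genes in rows, the four stage
        libraries in column order (earliest first).
    library_sizes
        Clean-tag totals per stage (the TPM denominators); keys must match
        the count columns.
    genome_size
        Total genes in the catalog, for percent-of-genome accounting;
        defaults to the number of rows.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: Mapping[str, int],
        genome_size: int | None = None,
    ):
        if counts.shape[1] != 4:
            raise InputError("expected exactly 4 stage columns")
        missing = set(counts.columns) - set(library_sizes)
        if missing:
            raise InputError(f"library sizes missing for stages: {sorted(missing)}")
        if (counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.stages = list(counts.columns)
        self.library_sizes = {s: int(library_sizes[s]) for s in self.stages}
        if any(n <= 0 for n in self.library_sizes.values()):
            raise InputError("library sizes must be positive")
        self.genome_size = int(genome_size) if genome_size is not None else len(counts)
        if self.genome_size < len(counts):
            raise InputError("genome_size smaller than the count matrix")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[ExpressionProfile],
        genome_size: int | None = None,
    ) -> "DGEModel":
        """Build from four per-stage expression profiles (mapping output)."""
        if len(profiles) != 4:
            raise InputError("expected exactly 4 profiles")
        counts = merge_profiles(profiles)
        sizes = {p.library_id: p.total_clean for p in profiles}
        return cls(counts, sizes, genome_size=genome_size)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        stages: Sequence[str],
        library_sizes: Mapping[str, int] | None = None,
        genome_size: int | None = None,
    ) -> "DGEModel":
        """Build from a merged count matrix (e.g. read back from TSV).

        Without explicit ``library_sizes`` the column sums are used, i.e.
        every clean tag is assumed to have been assigned.
        """
        counts = df[list(stages)]
        sizes = (
            dict(library_sizes)
            if library_sizes is not None
            else counts.sum(axis=0).to_dict()
        )
        return cls(counts, sizes, genome_size=genome_size)

    # -- fitting -----------------------------------------------------------

    @property
    def transitions(self) -> list[tuple[str, str, str]]:
        return [
            (f"T{i + 1}", self.stages[i], self.stages[i + 1])
            for i in range(len(self.stages) - 1)
        ]

    def _profile(self, stage: str) -> ExpressionProfile:
        return ExpressionProfile(
            library_id=stage,
            counts=self.counts[stage],
            total_clean=self.library_sizes[stage],
        )

    def fit(
        self,
        fdr: float = DEFAULT_FDR,
        min_log2fc: float = DEFAULT_MIN_LOG2FC,
        min_count: int = 1,
    ) -> "DGEResults":
        """Screen DEGs over every successive stage transition."""
        if not 0 < fdr <= 1:
            raise InputError("fdr must lie in (0, 1]")
        if min_log2fc < 0:
            raise InputError("min_log2fc must be non-negative")
        tests: dict[str, pd.DataFrame] = {}
        for label, s_earlier, s_later in self.transitions:
            tests[label] = screen(
                self._profile(s_earlier),
                self._profile(s_later),
                fdr=fdr,
                min_log2fc=min_log2fc,
                transition=label,
                min_count=min_count,
            )
        return DGEResults(self, tests, fdr=fdr, min_log2fc=min_log2fc, min_count=min_count)


class DGEResults:
    """Fitted DEG screen: test tables, DEG sets, summaries, stage sets."""

    def __init__(
        self,
        model: DGEModel,
        tests: Mapping[str, pd.DataFrame],
        fdr: float,
        min_log2fc: float,
        min_count: int,
    ):
        self.model = model
        self.tests = dict(tests)
        self.fdr = fdr
        self.min_log2fc = min_log2fc
        self.min_count = min_count

    def degs(self, transition: str) -> pd.DataFrame:
        """Declared DEGs of one transition (rows passing both thresholds)."""
        if transition not in self.tests:
            raise InputError(f"unknown transition {transition!r}")
        t = self.tests[transition]
        return t[t["is_deg"]]

    def transition_summary(self, transition: str) -> TransitionSummary:
        return summarize_transition(self.degs(transition))

    def expressed_sets(self) -> dict[str, set[str]]:
        c = self.model.counts
        return {s: set(c.index[c[s] >= self.min_count]) for s in self.model.stages}

    def venn(self) -> VennPartition:
        sets = self.expressed_sets()
        return venn_partition(
            [sets[s] for s in self.model.stages],
            genome_size=self.model.genome_size,
            labels=self.model.stages,
        )

    def venn_table(self) -> pd.DataFrame:
        return percentages(self.venn())

    def category_table(self, transition: str, cmap: CategoryMap, **kwargs) -> pd.DataFrame:
        return aggregate(self.degs(transition), cmap, **kwargs)

    def summary(self) -> str:
        """Human-readable run summary (thresholds, Venn headline, DEG tallies)."""
        lines = []
        m = self.model
        venn = self.venn()
        union = venn.union_size
        all4 = venn.region_counts[(True,) * 4]
        lines.append("Tag DGE screen")
        lines.append("=" * 60)
        lines.append(
            f"genes in catalog: {m.genome_size}; stages: {', '.join(m.stages)}"
        )
        lines.append(
            "clean tags/library: "
            + ", ".join(f"{s}={m.library_sizes[s]:,}" for s in m.stages)
        )
        lines.append(
            f"thresholds: FDR <= {self.fdr:g}, |log2FC| >= {self.min_log2fc:g}, "
            f"expressed = count >= {self.min_count}"
        )
        lines.append(
            f"expressed in >=1 stage: {union} "
            f"({100 * union / m.genome_size:.1f}% of genome); "
            f"in all four: {all4} "
            f"({100 * all4 / m.genome_size:.1f}% of genome, "
            f"{100 * all4 / union:.1f}% of expressed)"
        )
        lines.append("-" * 60)
        lines.append(
            f"{'transition':<12}{'DEGs':>7}{'up':>7}{'down':>7}{'on':>5}{'off':>5}{'%up':>8}"
        )
        for label, s1, s2 in m.transitions:
            ts = self.transition_summary(label)
            lines.append(
                f"{label + ' ' + s1 + '>' + s2:<12}{ts.n_total:>7}{ts.n_up:>7}"
                f"{ts.n_down:>7}{ts.n_on:>5}{ts.n_off:>5}{ts.pct_up:>8.1f}"
            )
        return "\n".join(lines)
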