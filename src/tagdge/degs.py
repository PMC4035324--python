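"""Differential expression screening between two tag libraries.

The per-gene test is the exact conditional count test of Audic & Claverie:
given x tags for a gene in a library of N1 clean tags, the count y in a
second library of N2 clean tags follows the predictive distribution

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative binomial with x+1 successes and success probability N1/(N1+N2).
The two-sided p-value is twice the smallest tail probability, evaluated in
both library orientations and capped at 1, which makes the test exactly
invariant under relabelling of the two libraries.  Multiplicity is handled
with Benjamini-Hochberg step-up FDR across all genes tested in a transition,
and a gene is declared differentially expressed when q <= 0.001 and
|log2 fold change| >= 1 (defaults; both configurable).

Fold changes are computed on TPM.  A gene detected in exactly one of the two
stages has an infinite fold change and is classed ``on`` or ``off`` instead
of a finite fold bin; finite bins are half-open: [2,4), [4,8), [8, inf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .quantify import ExpressionProfile

DEFAULT_FDR = 0.001
DEFAULT_MIN_LOG2FC = 1.0

FC_CLASSES = ("lt2", "2-4", "4-8", "8plus", "on", "off")


def _tails(x: np.ndarray, y: np.ndarray, n1: float, n2: float):
    """Lower/upper tail probabilities of y given x under the predictive NB."""
    p_success = n1 / (n1 + n2)
    lower = sps.nbinom.cdf(y, x + 1, p_success)
    upper = sps.nbinom.sf(y - 1, x + 1, p_success)
    return lower, upper


def count_test(
    x: int | np.ndarray,
    y: int | np.ndarray,
    n1: float,
    n2: float,
) -> float | np.ndarray:
    """Exact two-library count test; two-sided p-value.

    Vectorized over ``x`` and ``y``.  Symmetric under the simultaneous swap
    (x, N1) <-> (y, N2) because both orientations' tails enter the minimum.

    Raises
    ------
    InputError
        On negative counts or non-positive library sizes.
    """
    x_arr = np.asarray(x)
    y_arr = np.asarray(y)
    if np.any(x_arr < 0) or np.any(y_arr < 0):
        raise InputError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise InputError("library sizes must be positive")
    lo_a, up_a = _tails(x_arr, y_arr, n1, n2)
    lo_b, up_b = _tails(y_arr, x_arr, n2, n1)
    p = 2.0 * np.minimum.reduce([lo_a, up_a, lo_b, up_b])
    p = np.minimum(p, 1.0)
    if np.isscalar(x) and np.isscalar(y):
        return float(p)
    return p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of m * p_(j) / j, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def classify_fold(log2fc: float, count_x: int, count_y: int) -> str:
    """Fold-change class of one gene from its log2 fold change and counts."""
    if count_x == 0 and count_y > 0:
        return "on"
    if count_y == 0 and count_x > 0:
        return "off"
    a = abs(log2fc)
    if a < 1:
        return "lt2"
    if a < 2:
        return "2-4"
    if a < 3:
        return "4-8"
    return "8plus"


def screen(
    earlier: ExpressionProfile,
    later: ExpressionProfile,
    fdr: float = DEFAULT_FDR,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    transition: str = "",
    min_count: int = 1,
) -> pd.DataFrame:
    """Test every gene expressed in at least one of the two stages.

    Returns one row per tested gene with columns ``gene_id, transition,
    count_x, count_y, tpm_x, tpm_y, log2fc, p_value, q_value, direction,
    fc_class, is_deg``.  ``is_deg`` is True when q <= fdr and the fold
    criterion holds (|log2fc| >= min_log2fc; on/off genes always satisfy it).
    """
    if not earlier.counts.index.equals(later.counts.index):
        raise InputError("expression profiles do not share a gene universe")
    if earlier.total_clean <= 0 or later.total_clean <= 0:
        raise InputError("both libraries need positive clean-tag totals")

    x = earlier.counts.to_numpy()
    y = later.counts.to_numpy()
    tested = (x >= min_count) | (y >= min_count)
    genes = earlier.counts.index[tested]
    x, y = x[tested], y[tested]
    n1, n2 = earlier.total_clean, later.total_clean

    tpm_x = x * 1e6 / n1
    tpm_y = y * 1e6 / n2
    with np.errstate(divide="ignore"):
        log2fc = np.log2(tpm_y) - np.log2(tpm_x)

    p = count_test(x, y, n1, n2)
    q = bh_adjust(p)

    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    fc_class = np.array(
        [classify_fold(fc, cx, cy) for fc, cx, cy in zip(log2fc, x, y)],
        dtype=object,
    )
    on_off = (fc_class == "on") | (fc_class == "off")
    passes_fold = on_off | (np.abs(log2fc) >= min_log2fc)
    is_deg = (q <= fdr) & passes_fold

    return pd.DataFrame(
        {
            "gene_id": genes,
            "transition": transition,
            "count_x": x,
            "count_y": y,
            "tpm_x": tpm_x,
            "tpm_y": tpm_y,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "fc_class": fc_class,
            "is_deg": is_deg,
        }
    ).set_index("gene_id")


@dataclass
class TransitionSummary:
    """Direction and fold-class tallies of the DEGs of one transition."""

    transition: str
    n_up: int = 0
    n_down: int = 0
    n_on: int = 0
    n_off: int = 0
    class_counts: dict = field(default_factory=dict)  # (direction, fc_class) -> n

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    @property
    def pct_up(self) -> float:
        return 100.0 * self.n_up / self.n_total if self.n_total else 0.0

    @property
    def pct_down(self) -> float:
        return 100.0 * self.n_down / self.n_total if self.n_total else 0.0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": d, "fc_class": c, "n": n}
            for (d, c), n in sorted(self.class_counts.items())
        ]
        return pd.DataFrame(rows, columns=["direction", "fc_class", "n"])


def summarize_transition(records: pd.DataFrame) -> TransitionSummary:
    """Tally the DEGs of one transition by direction and fold class.

    ``records`` must come from a single transition; rows with
    ``is_deg == False`` (if present) are ignored.
    """
    transitions = set(records["transition"].unique()) if len(records) else set()
    if len(transitions) > 1:
        raise InputError(f"records mix transitions: {sorted(transitions)}")
    degs = records[records["is_deg"]] if "is_deg" in records.columns else records
    summary = TransitionSummary(transition=next(iter(transitions), ""))
    for _, row in degs.iterrows():
        d = row["direction"]
        c = row["fc_class"]
        if d == "up":
            summary.n_up += 1
        elif d == "down":
            summary.n_down += 1
        if c == "on":
            summary.n_on += 1
        elif c == "off":
            summary.n_off += 1
        key = (d, c)
        summary.class_counts[key] = summary.class_counts.get(key, 0) + 1
    return summary
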