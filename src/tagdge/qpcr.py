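"""Relative quantification of qPCR data by the 2^-ddCt (Livak) method.

Per stage, replicate Ct values are averaged on the Ct scale, the target
gene's mean Ct is normalized to a reference gene (dCt = Ct_target -
Ct_reference), re-expressed relative to a calibrator stage
(ddCt = dCt_stage - dCt_calibrator) and converted to a relative quantity
RQ = 2^-ddCt.  The calibrator's RQ is exactly 1 by construction.  No
amplification-efficiency correction is applied.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError

CT_COLUMNS = ("gene_id", "stage", "replicate", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table TSV with columns gene_id, stage, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return df


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise InputError("Ct values must be positive")
    return table


def relative_expression(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression of ``target`` across stages.

    Returns a DataFrame indexed by stage with columns ``dct``, ``ddct``,
    ``rq``.  Raises :class:`InputError`, naming the stage, when the
    reference gene is missing where the target was measured.
    """
    table = _validate(table)
    target_rows = table[table["gene_id"] == target]
    if target_rows.empty:
        raise InputError(f"target gene {target!r} not in the Ct table")
    ref_rows = table[table["gene_id"] == reference]
    stages = list(dict.fromkeys(target_rows["stage"]))
    if calibrator not in stages:
        raise InputError(f"calibrator stage {calibrator!r} not measured for {target!r}")

    mean_target = target_rows.groupby("stage")["ct"].mean()
    mean_ref = ref_rows.groupby("stage")["ct"].mean()
    for stage in stages:
        if stage not in mean_ref.index:
            raise InputError(
                f"reference gene {reference!r} not measured in stage {stage!r}"
            )
    dct = mean_target.loc[stages] - mean_ref.loc[stages]
    ddct = dct - dct.loc[calibrator]
    rq = 2.0 ** (-ddct)
    out = pd.DataFrame({"dct": dct, "ddct": ddct, "rq": rq})
    out.index.name = "stage"
    return out
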