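"""Gel-band quantification: percent-of-signal and normalized fold change.

percent_of_signal converts band intensities from one primer pair/lane to
percentages of their sum. fold_change normalizes a target band by a
control gene (RpL32 by default) within the same PCR replicate and divides
by the same ratio in the reference condition; cross-replicate ratios are
refused.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_CONTROL_GENE = "RpL32"


def percent_of_signal(intensities: Sequence[float]) -> list[float]:
    """100 * band / sum(bands) for each band of a primer pair."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one band required")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero intensities: percent of signal undefined")
    return list(100.0 * arr / total)


def fold_change(sample_target: float, sample_control_gene: float,
                ref_target: float, ref_control_gene: float) -> float:
    """(sample target / sample control gene) / (ref target / ref control gene)."""
    for label, v in (("sample_control_gene", sample_control_gene),
                     ("ref_target", ref_target),
                     ("ref_control_gene", ref_control_gene)):
        if v <= 0:
            raise ValueError(f"non-positive intensity in {label}: {v}")
    if sample_target < 0:
        raise ValueError(f"negative intensity in sample_target: {sample_target}")
    return (sample_target / sample_control_gene) / (ref_target / ref_control_gene)


def fold_change_table(bands: pd.DataFrame, target: str,
                      reference_condition: str,
                      control_gene: str = DEFAULT_CONTROL_GENE) -> pd.DataFrame:
    """Fold change of a target band vs a reference condition, per replicate.

    ``bands`` columns: condition, replicate, target, intensity. Each
    (condition, replicate) needs one row for the target and one for the
    control gene; replicate pairing is mandatory — a replicate missing its
    reference-condition measurements is an error.
    """
    required = {"condition", "replicate", "target", "intensity"}
    if not required <= set(bands.columns):
        raise ValueError(f"band table must have columns {sorted(required)}")

    def intensity(cond: str, rep, tgt: str) -> float:
        sel = bands[(bands["condition"] == cond) & (bands["replicate"] == rep)
                    & (bands["target"] == tgt)]
        if len(sel) != 1:
            raise ValueError(
                f"expected one {tgt} measurement for ({cond}, replicate {rep}), "
                f"found {len(sel)}")
        return float(sel["intensity"].iloc[0])

    rows = []
    for cond in bands["condition"].unique():
        if cond == reference_condition:
            continue
        reps = bands.loc[bands["condition"] == cond, "replicate"].unique()
        for rep in reps:
            fc = fold_change(
                intensity(cond, rep, target),
                intensity(cond, rep, control_gene),
                intensity(reference_condition, rep, target),
                intensity(reference_condition, rep, control_gene),
            )
            rows.append({"condition": cond, "replicate": rep,
                         "target": target, "fold_change": fc})
    return pd.DataFrame(rows)


def percent_of_signal_table(bands: pd.DataFrame,
                            group_cols: Sequence[str] = ("condition", "replicate"),
                            ) -> pd.DataFrame:
    """Percent of signal within each (primer pair/lane) group of a table."""
    out = bands.copy()
    grouped = out.groupby(list(group_cols))["intensity"]
    totals = grouped.transform("sum")
    if (totals == 0).any():
        bad = out.loc[totals == 0, list(group_cols)].drop_duplicates()
        raise ValueError(f"all-zero intensity groups: {bad.to_dict('records')}")
    out["percent"] = 100.0 * out["intensity"] / totals
    return out
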