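"""Copy-number ratio statistics from multiplex fragment quantifications.

Each sample contributes abundances for a mitochondrial fragment (M), an
X-chromosome fragment and an autosomal control fragment on chromosome 22.
The X/22 and M/22 ratios are standardized to Z-scores within each assay
batch (sample mean and n-1 standard deviation), removing batch-scale
effects before any group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult


@dataclass
class FragmentQuant:
    sample_id: str
    batch: str
    quant_m: float
    quant_x: float
    quant_22: float
    sex: str = ""
    genotype: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.quant_m, self.quant_x) <= 0 or self.quant_22 <= 0:
            raise ValueError(
                f"{self.sample_id}: fragment abundances must be positive"
            )


def quant_table(quants: list[FragmentQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [q.sample_id for q in quants],
            "batch": [q.batch for q in quants],
            "quant_m": [q.quant_m for q in quants],
            "quant_x": [q.quant_x for q in quants],
            "quant_22": [q.quant_22 for q in quants],
            "sex": [q.sex for q in quants],
            "genotype": [q.genotype for q in quants],
        }
    ).set_index("sample_id")


def ratio_z(quants: list[FragmentQuant]) -> pd.DataFrame:
    """X/22 and M/22 ratios with per-batch Z-standardization.

    Returns a frame indexed by sample with columns x22_ratio, m22_ratio,
    x22_z, m22_z plus the grouping columns carried through.  Every batch
    needs at least two samples for a defined standard deviation.
    """
    df = quant_table(quants)
    df["x22_ratio"] = df["quant_x"] / df["quant_22"]
    df["m22_ratio"] = df["quant_m"] / df["quant_22"]
    for batch, sub in df.groupby("batch"):
        if len(sub) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples")
    for col in ("x22_ratio", "m22_ratio"):
        zcol = col.replace("_ratio", "_z")
        grp = df.groupby("batch")[col]
        df[zcol] = (df[col] - grp.transform("mean")) / grp.transform(lambda s: s.std(ddof=1))
    return df[["batch", "sex", "genotype", "x22_ratio", "m22_ratio", "x22_z", "m22_z"]]


def group_test(
    z: pd.DataFrame, grouping: str, value_column: str = "m22_z"
) -> AssociationResult:
    """Two-sided Welch t-test of a Z-score column between two groups.

    ``grouping`` names a column of the ratio_z frame (``sex`` or
    ``genotype``); the estimate is the difference of group means (second
    level minus first, levels sorted).
    """
    if grouping not in z.columns:
        raise ValueError(f"no column {grouping!r} in ratio table")
    sub = z[[grouping, value_column]].dropna()
    levels = sorted(sub[grouping].unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    a = sub.loc[sub[grouping] == levels[0], value_column].to_numpy()
    b = sub.loc[sub[grouping] == levels[1], value_column].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(b, a, equal_var=False)
    est = float(b.mean() - a.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    return AssociationResult(
        predictor_id=f"{grouping}:{levels[1]}_vs_{levels[0]}",
        outcome_id=value_column,
        estimate=est,
        se=se,
        p=float(p),
        q=float(p),
        n=len(sub),
    )
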