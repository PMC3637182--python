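"""Relative qPCR quantification by the delta-delta-Ct method.

Per sample, dCt = Ct_target - Ct_reference (reference = endogenous control
gene, e.g. beta-actin); ddCt is the difference of group-mean dCt values
between condition and control, and fold change = 2^(-ddCt). A two-sided
two-sample t test on the per-sample dCt values accompanies the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class QpcrResult:
    delta_ct: pd.Series  # per-sample dCt, indexed by sample id
    group_mean_minus_dct: dict  # condition -> mean(-dCt)
    ddct: float
    fold_change: float
    t_statistic: float
    p_value: float
    condition: str
    control: str
    n_excluded: int


def qpcr_fold_change(
    ct_table: pd.DataFrame,
    condition: str,
    control: str,
    sample_col: str = "sample_id",
    condition_col: str = "condition",
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
) -> QpcrResult:
    """Fold change of ``condition`` relative to ``control``.

    Samples missing the reference-gene Ct are excluded with a warning.
    """
    df = ct_table.copy()
    missing = df[reference_col].isna() | df[target_col].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} sample(s) with missing Ct values",
            stacklevel=2,
        )
        df = df[~missing]
    for grp in (condition, control):
        if not (df[condition_col] == grp).any():
            raise ValueError(f"no samples for group {grp!r}")
    dct = df[target_col] - df[reference_col]
    dct.index = df[sample_col]
    grp_cond = dct[(df[condition_col] == condition).to_numpy()]
    grp_ctrl = dct[(df[condition_col] == control).to_numpy()]
    ddct = float(grp_cond.mean() - grp_ctrl.mean())
    t, p = sps.ttest_ind(grp_cond, grp_ctrl)
    return QpcrResult(
        delta_ct=dct,
        group_mean_minus_dct={condition: float(-grp_cond.mean()), control: float(-grp_ctrl.mean())},
        ddct=ddct,
        fold_change=float(2.0 ** (-ddct)),
        t_statistic=float(t),
        p_value=float(p),
        condition=condition,
        control=control,
        n_excluded=int(missing.sum()),
    )
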