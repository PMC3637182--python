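"""Study-level time-to-event summary table.

One row per endpoint (behavioral onsets and survival): per-arm Kaplan-Meier
medians and restricted means, the asymptotic log-rank and Wilcoxon p-values,
and the combined max-statistic permutation p-value. Endpoints are reported
without multiplicity adjustment, as is conventional for this study type; a
Holm-adjusted column for the combined p is emitted alongside, clearly
labeled, for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .km import km_estimate
from .ranktests import SurvivalSample, combined_permutation_test


def samples_from_frames(events: pd.DataFrame, survival: pd.DataFrame) -> dict:
    """Assemble per-endpoint two-arm samples from the events CSV (mouse_id,
    endpoint, age_days, observed) and the survival CSV (mouse_id, arm,
    age_days, event)."""
    arm_of = survival.set_index("mouse_id")["arm"]
    samples = {}
    for endpoint, grp in events.groupby("endpoint", sort=True):
        samples[endpoint] = SurvivalSample(
            times=grp["age_days"].to_numpy(float),
            events=grp["observed"].to_numpy(bool),
            groups=arm_of.loc[grp["mouse_id"]].to_numpy(),
        )
    samples["survival"] = SurvivalSample.from_frame(survival)
    return samples


def time_to_event_table(
    samples: dict, B: int = 2000, seed: int | None = None
) -> pd.DataFrame:
    """Table of medians, restricted means and p-values per endpoint."""
    rows = []
    for endpoint, sample in samples.items():
        labels = list(sample.group_labels)
        res = combined_permutation_test(sample, B=B, seed=seed)
        row = {"endpoint": endpoint}
        for g in labels:
            sel = sample.groups == g
            km = km_estimate(sample.times[sel], sample.events[sel])
            row[f"median_{g}"] = km.median if km.median is not None else np.nan
            row[f"mean_{g}"] = km.restricted_mean
        row["p_logrank"] = res.p_logrank_asymptotic
        row["p_wilcoxon"] = res.p_wilcoxon_asymptotic
        row["p_combined"] = res.p_permutation
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_combined_holm"] = multipletests(table["p_combined"], method="holm")[1]
    return table
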