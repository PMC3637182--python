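"""Censored two-sample rank tests and the combined permutation test.

The log-rank test weights all event times equally; the Gehan-Breslow
generalization of the Wilcoxon test weights each event time by the number
at risk and so emphasizes early differences. Rather than choosing a
weighting a priori, the combined statistic takes the maximum of the two
absolute standardized statistics, M = max(|Z_logrank|, |Z_wilcoxon|), and
assesses significance by permuting group labels — exactly (all label
arrangements) when their number is small, by Monte Carlo otherwise. The
trade is a modest loss of power against either pure alternative for
sensitivity to both early- and late-diverging survival differences.

Conventions: subjects censored at t leave the risk set after t; the
hypergeometric variance at an event time with a single subject at risk is
0; permutation ties count toward rejection; the Monte Carlo p-value uses
the add-one estimator (1 + #{M_b >= M_obs}) / (B + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class SurvivalSample:
    """(time, event, group) triples for a two-arm censored comparison."""

    times: np.ndarray
    events: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        self.groups = np.asarray(self.groups)
        if not (len(self.times) == len(self.events) == len(self.groups)):
            raise ValueError("times, events, groups must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("times must be > 0")

    @property
    def group_labels(self) -> np.ndarray:
        return np.unique(self.groups)

    def require_two_groups(self) -> None:
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 non-empty groups, got {list(labels)}")

    @classmethod
    def from_frame(cls, df, time_col="age_days", event_col="event", group_col="arm"):
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy(), df[group_col].to_numpy())


@dataclass
class RiskTableRow:
    t_j: float
    n_j: int
    n1j: int
    d_j: int
    d1j: int
    e1j: float
    v_j: float


@dataclass
class TwoSampleTestResult:
    z_logrank: float
    z_wilcoxon: float
    m_observed: float
    p_permutation: float
    n_permutations: int
    seed: int | None
    exhaustive: bool
    p_logrank_asymptotic: float  # reference only
    p_wilcoxon_asymptotic: float  # reference only
    wilcoxon_weight: str = "gehan"
    n_degenerate_permutations: int = 0


class _RiskArrays:
    """Distinct event times with at-risk/event indicator matrices; all
    label-dependent quantities follow by matrix products, which is what makes
    exhaustive/Monte-Carlo permutation cheap."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        self.event_times = np.unique(times[events])
        if self.event_times.size == 0:
            self.n_j = np.zeros(0)
            self.d_j = np.zeros(0)
            self.at_risk = np.zeros((0, len(times)), dtype=float)
            self.event_at = np.zeros((0, len(times)), dtype=float)
            return
        et = self.event_times[:, None]
        self.at_risk = (times[None, :] >= et).astype(float)
        self.event_at = ((times[None, :] == et) & events[None, :]).astype(float)
        self.n_j = self.at_risk.sum(axis=1)
        self.d_j = self.event_at.sum(axis=1)

    def weights(self, kind: str) -> np.ndarray:
        if kind == "logrank":
            return np.ones_like(self.n_j)
        if kind == "gehan":
            return self.n_j
        if kind == "peto":
            # pooled modified Kaplan-Meier survival S~(t_j)
            return np.cumprod(1.0 - self.d_j / (self.n_j + 1.0))
        raise ValueError(f"unknown wilcoxon weight {kind!r}")

    def z_for_labels(self, labels: np.ndarray, kind: str) -> np.ndarray:
        """Standardized weighted statistic for each column of ``labels``
        (n x B matrix of 0/1 group-1 indicators); NaN where variance is 0."""
        if self.event_times.size == 0:
            raise ValueError("sample contains no events; rank tests undefined")
        n1 = self.at_risk @ labels
        d1 = self.event_at @ labels
        n = self.n_j[:, None]
        d = self.d_j[:, None]
        e1 = d * n1 / n
        denom = n * n * np.maximum(n - 1.0, 1.0)
        v = np.where(n > 1, n1 * (n - n1) * d * (n - d) / denom, 0.0)
        w = self.weights(kind)[:, None]
        u = (w * (d1 - e1)).sum(axis=0)
        var = (w * w * v).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(var > 0, u / np.sqrt(var), np.nan)


def _group1_indicator(sample: SurvivalSample) -> np.ndarray:
    sample.require_two_groups()
    return (sample.groups == sample.group_labels[0]).astype(float)


def build_risk_table(sample: SurvivalSample) -> list[RiskTableRow]:
    """One row per distinct event time; censored times shape the risk sets
    only. Group 1 is the first group label in sorted order."""
    label = _group1_indicator(sample)
    ra = _RiskArrays(sample.times, sample.events)
    rows = []
    for j, t in enumerate(ra.event_times):
        n, d = ra.n_j[j], ra.d_j[j]
        n1 = float(ra.at_risk[j] @ label)
        d1 = float(ra.event_at[j] @ label)
        e1 = d * n1 / n
        v = n1 * (n - n1) * d * (n - d) / (n * n * (n - 1)) if n > 1 else 0.0
        rows.append(RiskTableRow(float(t), int(n), int(n1), int(d), int(d1), e1, v))
    return rows


def _z_from_table(table: list[RiskTableRow], weight_fn) -> float:
    if not table:
        raise ValueError("empty risk table (no events)")
    u = sum(weight_fn(r) * (r.d1j - r.e1j) for r in table)
    var = sum(weight_fn(r) ** 2 * r.v_j for r in table)
    if var <= 0:
        raise ZeroDivisionError("zero total variance; Z undefined")
    return u / math.sqrt(var)


def logrank_z(table: list[RiskTableRow]) -> float:
    """Z = sum(d1j - e1j) / sqrt(sum v_j): every event time weighted equally."""
    return _z_from_table(table, lambda r: 1.0)


def gehan_wilcoxon_z(table: list[RiskTableRow]) -> float:
    """Gehan-Breslow weighting w_j = n_j, emphasizing early event times."""
    return _z_from_table(table, lambda r: r.n_j)


def combined_permutation_test(
    sample: SurvivalSample,
    B: int = 2000,
    seed: int | None = None,
    wilcoxon_weight: str = "gehan",
    exhaustive_limit: int = 20_000,
) -> TwoSampleTestResult:
    """Max(|Z_logrank|, |Z_wilcoxon|) with a permutation null.

    All C(n, n1) label arrangements are enumerated when their count is at
    most ``exhaustive_limit`` (the p-value is then exact); otherwise ``B``
    Monte Carlo permutations with the add-one estimator. Permutations whose
    statistics are degenerate (zero variance) contribute M_b = 0, with a
    logged warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    label = _group1_indicator(sample)
    ra = _RiskArrays(sample.times, sample.events)
    z_obs = ra.z_for_labels(label[:, None], "logrank")[0]
    zw_obs = ra.z_for_labels(label[:, None], wilcoxon_weight)[0]
    if np.isnan(z_obs) or np.isnan(zw_obs):
        raise ZeroDivisionError("observed statistics degenerate (zero variance)")
    m_obs = max(abs(z_obs), abs(zw_obs))

    n = len(sample.times)
    n1 = int(label.sum())
    exhaustive = math.comb(n, n1) <= exhaustive_limit

    if exhaustive:
        arrangements = np.zeros((n, math.comb(n, n1)))
        for b, idx in enumerate(combinations(range(n), n1)):
            arrangements[list(idx), b] = 1.0
    else:
        rng = np.random.default_rng(seed)
        arrangements = np.zeros((n, B))
        for b in range(B):
            arrangements[rng.permutation(n)[:n1], b] = 1.0

    z_lr = ra.z_for_labels(arrangements, "logrank")
    z_w = ra.z_for_labels(arrangements, wilcoxon_weight)
    m = np.fmax(np.abs(z_lr), np.abs(z_w))
    n_degen = int(np.isnan(m).sum())
    if n_degen:
        warnings.warn(
            f"{n_degen} degenerate permutations (zero variance) counted as M_b = 0",
            stacklevel=2,
        )
        m = np.nan_to_num(m, nan=0.0)

    hits = int((m >= m_obs - 1e-12).sum())
    if exhaustive:
        p = hits / m.size  # the observed arrangement is one of the M_b
    else:
        p = (1 + hits) / (m.size + 1)

    return TwoSampleTestResult(
        z_logrank=float(z_obs),
        z_wilcoxon=float(zw_obs),
        m_observed=float(m_obs),
        p_permutation=float(p),
        n_permutations=int(m.size),
        seed=seed,
        exhaustive=exhaustive,
        p_logrank_asymptotic=float(2 * sps.norm.sf(abs(z_obs))),
        p_wilcoxon_asymptotic=float(2 * sps.norm.sf(abs(zw_obs))),
        wilcoxon_weight=wilcoxon_weight,
        n_degenerate_permutations=n_degen,
    )
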