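"""Product-limit (Kaplan-Meier) estimation for one arm.

The median is the first event time at which the survival estimate drops to
0.5 or below (None if never reached). The mean under right censoring is
reported as the restricted mean survival time — the integral of S(t) up to
the largest observed time — the only well-defined nonparametric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KMEstimate:
    event_times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    median: float | None
    restricted_mean: float
    t_max: float  # largest observed (event or censored) time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times, events) -> KMEstimate:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    event_times = np.unique(times[events])
    s = 1.0
    surv = []
    for t in event_times:
        n_at_risk = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    surv = np.asarray(surv)
    median = None
    below = np.nonzero(surv <= 0.5)[0]
    if below.size:
        median = float(event_times[below[0]])
    t_max = float(times.max())
    # integral of the step function from 0 to t_max
    knots = np.concatenate([[0.0], event_times, [t_max]])
    heights = np.concatenate([[1.0], surv])
    widths = np.clip(np.diff(knots), 0.0, None)
    rmst = float((heights * widths).sum())
    return KMEstimate(
        event_times=event_times,
        survival=surv,
        median=median,
        restricted_mean=rmst,
        t_max=t_max,
    )
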