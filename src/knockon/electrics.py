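"""Conductance, confidence intervals, selectivity and fold changes.

Net permeation event counts are converted to conductance as
``G = N_net * e / (t * |V|)`` with the elementary charge fixed at the 2019 SI
exact value.  Replica averages carry Student-t 95% confidence intervals; the
pooled estimate (total net events over total time) is reported alongside,
since headline single-number conductances in the literature are usually of
the pooled form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .model import ConductanceEstimate, DomainError, Species

__all__ = [
    "E_CHARGE",
    "conductance",
    "mean_ci",
    "ReplicaSummary",
    "SelectivityEstimate",
    "permeability_ratio",
    "fold_change",
]

#: elementary charge, C (2019 SI exact value)
E_CHARGE = 1.602176634e-19


def conductance(net_events: float, duration_us: float, voltage_mv: float) -> float:
    """Conductance in pS from a net outward event count.

    For runs at negative voltage the inward conductance is the negative of
    the net-outward-based value, so a channel passing current in the direction
    of the driving force always reports a positive conductance.
    """
    if duration_us <= 0:
        raise DomainError("duration must be positive")
    if voltage_mv == 0:
        raise DomainError("voltage must be nonzero for a conductance")
    g = net_events * E_CHARGE / (duration_us * 1e-6 * abs(voltage_mv) * 1e-3)
    if voltage_mv < 0:
        g = -g
    return g * 1e12  # S -> pS


def mean_ci(per_replica: Sequence[float], confidence: float = 0.95) -> ConductanceEstimate:
    """Replica mean with a Student-t confidence interval.

    With a single replica the mean is returned and the CI flagged undefined
    (NaN halfwidth); with zero replicas this is a domain error.
    """
    values = np.asarray(list(per_replica), dtype=float)
    n = values.size
    if n == 0:
        raise DomainError("need at least one replica")
    mean = float(values.mean())
    if n == 1:
        return ConductanceEstimate(values, mean, float("nan"), 1)
    s = float(values.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return ConductanceEstimate(values, mean, tcrit * s / np.sqrt(n), n)


@dataclass
class ReplicaSummary:
    """Net outward events per species for one replica, with its metadata."""

    net_outward: Dict[str, int]
    duration_us: float
    voltage_mv: float

    def __post_init__(self) -> None:
        if self.duration_us <= 0:
            raise DomainError("duration must be positive")

    def conductance(self, species: Species) -> float:
        s = Species.coerce(species).value
        return conductance(
            self.net_outward.get(s, 0), self.duration_us, self.voltage_mv
        )


@dataclass
class SelectivityEstimate:
    """Permeability ratio PNa/PK; ``ratio`` is None when the K side is zero."""

    ratio: Optional[float]
    method: str
    g_na: float
    g_k: float


def permeability_ratio(
    na_runs: Sequence[ReplicaSummary],
    k_runs: Sequence[ReplicaSummary],
    method: str = "conductance_ratio",
) -> SelectivityEstimate:
    """PNa/PK from single-ion runs.

    ``conductance_ratio`` (default) divides the replica-mean Na+ conductance
    by the replica-mean K+ conductance; ``count_ratio`` divides pooled event
    rates, which is preferable for strongly unequal run durations.
    """
    if method == "conductance_ratio":
        g_na = mean_ci([r.conductance(Species.NA) for r in na_runs]).mean
        g_k = mean_ci([r.conductance(Species.K) for r in k_runs]).mean
    elif method == "count_ratio":
        g_na = sum(r.net_outward.get("NA", 0) for r in na_runs) / sum(
            r.duration_us for r in na_runs
        )
        g_k = sum(r.net_outward.get("K", 0) for r in k_runs) / sum(
            r.duration_us for r in k_runs
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    ratio = g_na / g_k if g_k > 0 else None
    return SelectivityEstimate(ratio, method, g_na, g_k)


def fold_change(g_ref: float, g_mut: float) -> float:
    """Conductance reduction factor G_ref / G_mut; infinite when G_mut is 0."""
    if g_mut == 0:
        return float("inf")
    return g_ref / g_mut
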