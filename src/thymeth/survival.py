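"""Disease-free survival comparison and unsupervised cohort clustering.

Kaplan-Meier product-limit curves and the log-rank test are computed with
lifelines; hierarchical clustering of samples uses 1 - Pearson correlation
distance with average linkage over the most variable probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import BetaMatrix
from .qc import most_variable_probes

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "log_rank", "hier_cluster"]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.event_times) == len(self.survival) == len(self.at_risk)):
            raise ValueError("KM curve arrays must have equal length")
        if len(self.survival) and (
            np.any(np.diff(self.survival) > 1e-12) or self.survival[0] > 1 + 1e-12
        ):
            raise ValueError("survival must be non-increasing and start <= 1")

    def at(self, t: float) -> float:
        """S(t): the step-function value at time t (1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("need >=1 survival record")
    if (records["time_months"] <= 0).any():
        bad = records.index[records["time_months"] <= 0].tolist()[:5]
        raise ValueError(f"non-positive survival times for samples {bad}")
    return records


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``records`` has columns ``time_months`` and ``event`` (True when the
    recurrence was observed).  The curve is reported at the distinct event
    times; with no events, S(t) = 1 everywhere (empty arrays).
    """
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_months"], event_observed=records["event"].astype(bool))
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, kmf._label].to_numpy(dtype=float)
    return KMCurve(times, surv, ev["at_risk"].to_numpy(dtype=int))


def log_rank(groups: dict[str, pd.DataFrame]) -> LogRankResult:
    """Log-rank chi-square across >=2 survival groups (df = groups - 1).

    Uses the hypergeometric-variance form without continuity correction;
    when no group has any event the statistic is 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs >=2 groups")
    frames = []
    for name, rec in groups.items():
        rec = _check_records(rec)
        frames.append(
            pd.DataFrame(
                {
                    "time": rec["time_months"].to_numpy(dtype=float),
                    "event": rec["event"].astype(bool).to_numpy(),
                    "group": name,
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    df = len(groups) - 1
    if not pooled["event"].any():
        return LogRankResult(0.0, df, 1.0)
    res = multivariate_logrank_test(pooled["time"], pooled["group"], pooled["event"])
    return LogRankResult(float(res.test_statistic), df, float(res.p_value))


def hier_cluster(beta: BetaMatrix, k_probes: int, k_clusters: int) -> pd.Series:
    """Average-linkage clustering of samples on the most variable probes.

    Distance between samples is 1 - Pearson correlation over the top
    ``k_probes`` probes by variance.  The tree is cut at ``k_clusters``;
    labels are renumbered 1..k by order of each cluster's first sample, so
    the output is invariant to sample order up to that deterministic
    relabelling.
    """
    if k_clusters < 1 or k_clusters > beta.shape[1]:
        raise ValueError("k_clusters must lie in [1, n_samples]")
    top = most_variable_probes(beta, k_probes)
    X = beta.subset(probes=top).values.to_numpy().T  # samples x probes
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = beta.sample_ids[np.flatnonzero(sd == 0)].tolist()[:5]
        raise ValueError(f"constant sample vector(s), correlation undefined: {bad}")
    dist = 1.0 - np.corrcoef(X)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrise fp noise
    linkage = hierarchy.average(squareform(dist, checks=False))
    raw = hierarchy.fcluster(linkage, t=k_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    return pd.Series([relabel[l] for l in raw], index=beta.sample_ids, name="cluster")
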