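"""Probe-level quality filters for 450k beta matrices.

Five exclusion rules are applied, in a fixed order, to the analysis-ready
matrix: cross-reactive probes, probes overlapping common SNPs (minor allele
frequency > 5%), sex-associated probes, probes with a failed detection
p-value (> 0.05) in >= 5% of samples, and probes with low bead count (< 3)
in >= 5% of samples.  Each removed probe is attributed to the first rule
that matched it.

Normalisation (e.g. beta-mixture quantile normalisation) and batch
correction are deliberately not implemented here; `filter_probes` accepts a
``normalizer`` callable hook so an externally normalised matrix, or a
published method, can be plugged in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ProbeAnnotation, QCMetrics

__all__ = ["FilterReport", "filter_probes", "most_variable_probes"]

RULE_ORDER = ("cross_reactive", "snp", "sex", "detection_p", "bead_count")


@dataclass
class FilterReport:
    """Per-rule removal counts for one `filter_probes` run."""

    n_input: int
    n_retained: int
    removed: dict[str, int]
    rule_order: tuple[str, ...] = RULE_ORDER
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.removed.values()) != self.n_input:
            raise ValueError("filter report counts do not partition the input probes")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": dict(self.removed),
            "rule_order": list(self.rule_order),
            "params": dict(self.params),
        }


def filter_probes(
    beta: BetaMatrix,
    ann: ProbeAnnotation,
    qc: QCMetrics,
    *,
    detection_p_threshold: float = 0.05,
    sample_fraction: float = 0.05,
    min_bead_count: int = 3,
    normalizer: Callable[[BetaMatrix], BetaMatrix] | None = None,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the five probe-exclusion rules and return the retained matrix.

    The "in >= 5% of samples" count threshold is ``ceil(sample_fraction * n)``,
    the conservative reading when 5% of the cohort is not an integer.
    Probe order in the output is a subsequence of the input order.
    """
    missing_ann = beta.probe_ids.difference(ann.probe_ids)
    if len(missing_ann):
        raise ValueError(f"probes missing from annotation: {missing_ann.tolist()[:10]}")
    qc.check_aligned(beta)

    ann_t = ann.table.loc[beta.probe_ids]
    n_samples = beta.shape[1]
    n_fail_threshold = math.ceil(sample_fraction * n_samples)

    det_fail = (qc.detection_p.to_numpy() > detection_p_threshold).sum(axis=1)
    bead_fail = (qc.bead_count.to_numpy() < min_bead_count).sum(axis=1)

    rule_masks = {
        "cross_reactive": ann_t["cross_reactive"].to_numpy(),
        "snp": ann_t["snp_maf_gt_5pct"].to_numpy(),
        "sex": ann_t["sex_chromosome"].to_numpy(),
        "detection_p": det_fail >= n_fail_threshold,
        "bead_count": bead_fail >= n_fail_threshold,
    }

    removed = {}
    already = np.zeros(beta.shape[0], dtype=bool)
    for rule in RULE_ORDER:
        hit = rule_masks[rule] & ~already
        removed[rule] = int(hit.sum())
        already |= hit

    keep = beta.probe_ids[~already]
    out = beta.subset(probes=keep)
    if normalizer is not None:
        out = normalizer(out)
    report = FilterReport(
        n_input=beta.shape[0],
        n_retained=len(keep),
        removed=removed,
        params={
            "detection_p_threshold": detection_p_threshold,
            "sample_fraction": sample_fraction,
            "min_bead_count": min_bead_count,
            "n_fail_threshold": n_fail_threshold,
        },
    )
    return out, report


def most_variable_probes(beta: BetaMatrix, k: int) -> list[str]:
    """The k probes with largest cross-sample variance.

    Ties are broken by lexicographic probe id, so the result is
    deterministic even on constant matrices.  Variance is computed over
    non-missing samples (ddof=1).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > beta.shape[0]:
        raise ValueError(f"k={k} exceeds probe count {beta.shape[0]}")
    var = beta.values.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    order = sorted(zip(-var.to_numpy(), var.index.astype(str)))
    return [probe for _, probe in order[:k]]
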