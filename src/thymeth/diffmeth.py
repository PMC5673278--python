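"""Per-probe two-group differential methylation.

Effect size is the difference of group mean beta values (delta-beta); the
test statistic is a moderated t with empirical-Bayes variance shrinkage:
per-probe residual variances s_g^2 (d_g residual df) are shrunk toward a
prior (d0, s0^2) estimated by the method of moments on log s^2, giving

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g = delta_g / (s_tilde_g * sqrt(1/n_a + 1/n_b))

with two-sided p-values on d0 + d_g degrees of freedom.  A probe is called
differential (hyper- or hypomethylated) only when the Bonferroni-adjusted
p-value and the |delta-beta| threshold are both met.

Statistics are computed on beta values directly (not M-values) so that the
effect-size gate and the test share one scale; a Welch t is available as a
cross-check statistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import BetaMatrix, ProbeAnnotation, SampleMetadata, PROMOTER_REGIONS

__all__ = [
    "ContrastSpec",
    "delta_beta",
    "moderated_t",
    "welch_t",
    "squeeze_variances",
    "bonferroni",
    "call_differential",
    "context_summary",
    "exclusivity_sets",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("hyper", "hypo", "none")


@dataclass
class ContrastSpec:
    """A two-group contrast with its significance rules.

    ``group_a`` / ``group_b`` are lesion classes or the outcome groups
    WDTC_GP / WDTC_PP; delta-beta is mean(a) - mean(b).
    """

    group_a: str
    group_b: str = "NT"
    delta_threshold: float = 0.2
    p_threshold: float = 0.05
    statistic: str = "moderated_t"

    def __post_init__(self) -> None:
        if not (0 < self.delta_threshold <= 1):
            raise ValueError("delta_threshold must be in (0, 1]")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.statistic not in ("moderated_t", "welch_t"):
            raise ValueError(f"unknown statistic {self.statistic!r}")

    @property
    def name(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


def _group_arrays(beta: BetaMatrix, samples_a, samples_b) -> tuple[np.ndarray, np.ndarray]:
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise ValueError("both sample groups must be non-empty")
    a = beta.subset(samples=samples_a).values.to_numpy()
    b = beta.subset(samples=samples_b).values.to_numpy()
    return a, b


def delta_beta(beta: BetaMatrix, samples_a, samples_b) -> pd.Series:
    """Per-probe mean(a) - mean(b), pairwise-complete over samples."""
    a, b = _group_arrays(beta, samples_a, samples_b)
    with np.errstate(invalid="ignore"):
        d = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    return pd.Series(d, index=beta.probe_ids, name="delta_beta")


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(-dif / x < 1e-8):
            break
    return x


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-probe variances.

    Fits a scaled inverse chi-square prior (d0, s0^2) by matching the first
    two moments of log s^2 and returns (posterior variances, d0, s0^2).
    When the moment estimate of d0 is non-finite (observed spread of log
    variances no larger than expected under a common variance), all
    variances are shrunk fully to s0^2 (d0 = inf).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >=2 probes with positive residual variance to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar > 0:
        df_prior = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s0_2 = float(np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        logger.warning(
            "moment estimation of the prior df is non-finite; "
            "shrinking all variances fully to the common value"
        )
        df_prior = np.inf
        s0_2 = float(np.exp(emean))
    if np.isinf(df_prior):
        post = np.full_like(s2, s0_2)
    else:
        post = (df_prior * s0_2 + df * s2) / (df_prior + df)
        post = np.where(ok, post, s0_2)
    return post, df_prior, s0_2


def _group_moments(a: np.ndarray, b: np.ndarray):
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        ssa = np.nansum((a - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((b - mb[:, None]) ** 2, axis=1)
    return na, nb, ma, mb, ssa, ssb


def moderated_t(beta: BetaMatrix, samples_a, samples_b) -> pd.DataFrame:
    """Per-probe moderated t and two-sided p for mean(a) - mean(b).

    Requires >=2 samples per group; probes with fewer than 2 non-missing
    values in either group get NaN statistics and are excluded from the
    prior fit.
    """
    a, b = _group_arrays(beta, samples_a, samples_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >=2 samples for the moderated t")
    na, nb, ma, mb, ssa, ssb = _group_moments(a, b)
    df_resid = (na + nb - 2).astype(float)
    usable = (na >= 2) & (nb >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(usable, (ssa + ssb) / np.maximum(df_resid, 1), np.nan)
    post, df_prior, _ = squeeze_variances(
        np.where(usable, s2, np.nan), np.where(usable, df_resid, np.nan)
    )
    delta = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(post * (1.0 / na + 1.0 / nb))
        t = delta / se
    df_total = df_prior + df_resid
    if np.isinf(df_prior):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t = np.where(usable, t, np.nan)
    p = np.where(usable, p, np.nan)
    return pd.DataFrame(
        {"delta_beta": delta, "t_stat": t, "p_raw": p, "df_total": df_total},
        index=beta.probe_ids,
    )


def welch_t(beta: BetaMatrix, samples_a, samples_b) -> pd.DataFrame:
    """Per-probe Welch (unequal-variance) t as a cross-check statistic."""
    a, b = _group_arrays(beta, samples_a, samples_b)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    return pd.DataFrame(
        {"delta_beta": delta, "t_stat": res.statistic, "p_raw": res.pvalue},
        index=beta.probe_ids,
    )


def bonferroni(p_raw, m: int):
    """Bonferroni adjustment p_adj = min(1, m * p_raw); requires m >= #tests."""
    p = np.asarray(p_raw, dtype=float)
    if m < np.sum(~np.isnan(p)):
        raise ValueError(f"m={m} is smaller than the number of tests")
    adj = np.minimum(1.0, m * p)
    if isinstance(p_raw, pd.Series):
        return pd.Series(adj, index=p_raw.index, name="p_adj")
    return adj


def call_differential(
    contrast: ContrastSpec,
    beta: BetaMatrix,
    metadata: SampleMetadata,
    *,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Call per-probe differential methylation for one contrast.

    Returns a DataFrame (index = probe ids) with columns delta_beta,
    t_stat, p_raw, p_adj and direction; direction is hyper/hypo only when
    p_adj < p_threshold and |delta_beta| > delta_threshold.  ``n_tests``
    defaults to the number of probes in ``beta`` (the post-QC platform).
    """
    samples_a = metadata.resolve_group(contrast.group_a)
    samples_b = metadata.resolve_group(contrast.group_b)
    stat_fn = moderated_t if contrast.statistic == "moderated_t" else welch_t
    res = stat_fn(beta, samples_a, samples_b)
    m = n_tests if n_tests is not None else beta.shape[0]
    res["p_adj"] = bonferroni(res["p_raw"], m)
    significant = (res["p_adj"] < contrast.p_threshold) & (
        res["delta_beta"].abs() > contrast.delta_threshold
    )
    direction = np.where(
        significant & (res["delta_beta"] > 0),
        "hyper",
        np.where(significant & (res["delta_beta"] < 0), "hypo", "none"),
    )
    res["direction"] = direction
    res.attrs["contrast"] = contrast
    res.attrs["n_tests"] = m
    return res


_REGION_PRECEDENCE = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "intergenic")


def _primary_region(regions: tuple[str, ...]) -> str:
    for tok in _REGION_PRECEDENCE:
        if tok in regions:
            return tok
    return "intergenic"


def _collapse_location(regions: tuple[str, ...]) -> str:
    if any(r in PROMOTER_REGIONS for r in regions):
        return "promoter"
    if any(r in ("Body", "3UTR") for r in regions):
        return "body"
    return "intergenic"


def context_summary(
    result: pd.DataFrame, ann: ProbeAnnotation, *, collapse: bool = False
) -> dict[str, pd.DataFrame]:
    """Genomic-context proportions of the differential probes, by direction.

    Returns ``{"gene_region": ..., "island_relation": ...}``; each table has
    one column per direction (hyper/hypo) with proportions summing to 1.
    With ``collapse=True`` gene regions are grouped into promoter / body /
    intergenic (promoter wins when a multi-gene probe maps to both).
    """
    diff = result[result["direction"] != "none"]
    missing = diff.index.difference(ann.probe_ids)
    if len(missing):
        raise ValueError(f"annotations missing for probes: {missing.tolist()[:10]}")
    out: dict[str, pd.DataFrame] = {}
    if diff.empty:
        return {"gene_region": pd.DataFrame(), "island_relation": pd.DataFrame()}
    sub = ann.subset(diff.index).table
    region_fn = _collapse_location if collapse else _primary_region
    labels = {
        "gene_region": sub["gene_regions"].map(region_fn),
        "island_relation": sub["island_relation"],
    }
    for panel, lab in labels.items():
        tab = pd.crosstab(lab, diff["direction"])
        out[panel] = tab / tab.sum(axis=0)
    return out


def exclusivity_sets(results: dict[str, pd.DataFrame]) -> dict:
    """Exclusive and shared differential probes across lesion-class contrasts.

    A probe is exclusive to class c in direction d when it is called d in c
    and called none (or the opposite direction) in every other class.
    Shared sets are reported for every unordered class pair.
    """
    if len(results) < 2:
        raise ValueError("need >=2 contrasts for exclusivity analysis")
    calls = {
        cls: {
            "hyper": set(res.index[res["direction"] == "hyper"]),
            "hypo": set(res.index[res["direction"] == "hypo"]),
        }
        for cls, res in results.items()
    }
    exclusive = {}
    for cls in calls:
        exclusive[cls] = {}
        for d in ("hyper", "hypo"):
            others = set().union(*(calls[o][d] for o in calls if o != cls))
            exclusive[cls][d] = calls[cls][d] - others
    shared = {}
    for c1, c2 in itertools.combinations(sorted(calls), 2):
        shared[(c1, c2)] = {
            d: calls[c1][d] & calls[c2][d] for d in ("hyper", "hypo")
        }
    return {"exclusive": exclusive, "shared": shared}
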