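"""Synthetic 450k-style cohort generator.

Emulates the statistical structure the analysis pipeline assumes: bimodal
beta-value distributions (logit-normal mixture), lesion-class-specific
delta-beta shifts against normal thyroid, an attenuated poor-prognosis
signal shared with undifferentiated tumours on promoter probes, detection-p
and bead-count QC artifacts, manifest-style probe annotations, batch
labels, and recurrence/censoring times.

Group effects are applied on the logit scale; for every planted probe the
shift of the target group is calibrated on the realized draw (Brent root
finding) so the realized group-mean delta-beta equals the configured target
exactly.  Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datatypes import (
    BetaMatrix,
    ProbeAnnotation,
    QCMetrics,
    SampleMetadata,
)

__all__ = [
    "PlantedEffect",
    "PPPanelSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_survival",
]


@dataclass
class PlantedEffect:
    """A block of probes shifted in one target group relative to a reference.

    ``delta_beta`` is the signed realized group-mean difference
    (target - reference) on the beta scale; ``region`` may restrict the
    probes used to ``"promoter"`` annotated ones.
    """

    target: str
    n_probes: int
    delta_beta: float
    reference: str = "NT"
    region: str | None = None

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not (-1.0 < self.delta_beta < 1.0) or self.delta_beta == 0:
            raise ValueError("delta_beta target must be in (-1, 1) and non-zero")


@dataclass
class PPPanelSpec:
    """Poor-prognosis marker panel shared with undifferentiated tumours.

    ``n_probes`` promoter probes are shifted in PDTC/ATC vs NT by
    ``pdtc_delta`` (``n_hyper`` of them positively, the rest negatively) and
    in WDTC-PP vs WDTC-GP by ``attenuation * pdtc_delta`` with the same
    sign — the premise that recurrence-prone well-differentiated tumours
    share an attenuated version of the undifferentiated promoter signal.
    """

    n_probes: int = 21
    n_hyper: int = 4
    pdtc_delta: float = 0.35
    attenuation: float = 0.35

    def __post_init__(self) -> None:
        if not (0 <= self.n_hyper <= self.n_probes):
            raise ValueError("n_hyper must be between 0 and n_probes")
        if not (0 < self.pdtc_delta < 1) or not (0 < self.attenuation < 1):
            raise ValueError("pdtc_delta and attenuation must be in (0, 1)")

    @property
    def pp_delta(self) -> float:
        return self.attenuation * self.pdtc_delta


def _default_planted() -> list[PlantedEffect]:
    return [
        PlantedEffect("BTL", 120, +0.30),
        PlantedEffect("BTL", 30, -0.30),
        PlantedEffect("PTC", 200, -0.30),
        PlantedEffect("PTC", 30, +0.30),
        PlantedEffect("FTC_HCC", 150, +0.30),
        PlantedEffect("FTC_HCC", 50, -0.30),
        PlantedEffect("PDTC_ATC", 400, -0.35),
        PlantedEffect("PDTC_ATC", 100, +0.35),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Cohort sizes default to the design of the analysis: 50 NT, 17 BTL,
    60 PTC, 10 FTC/HCC, 4 PDTC/ATC, with the well-differentiated samples
    split into 48 good-prognosis (43 PTC + 5 FTC) and 8 poor-prognosis
    (6 PTC + 2 FTC) cases.
    """

    n_probes: int = 20000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"NT": 50, "BTL": 17, "PTC": 60, "FTC_HCC": 10, "PDTC_ATC": 4}
    )
    outcome_split: Mapping[str, int] = field(
        default_factory=lambda: {"GP_PTC": 43, "GP_FTC": 5, "PP_PTC": 6, "PP_FTC": 2}
    )
    planted_effects: Sequence[PlantedEffect] = field(default_factory=_default_planted)
    pp_panel: PPPanelSpec | None = field(default_factory=PPPanelSpec)
    # logit-scale beta mixture: (mode beta, weight) plus probe- and sample-level spread
    beta_modes: Sequence[tuple[float, float]] = ((0.10, 0.45), (0.50, 0.10), (0.85, 0.45))
    probe_mean_sd: float = 0.6
    sample_noise_sd: float = 0.45
    batch_effect_sd: float = 0.10
    n_batches: int = 2
    qc_artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: {"detection_p": 0.02, "bead_count": 0.02}
    )
    annotation_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"promoter": 0.40, "body": 0.35, "intergenic": 0.25}
    )
    island_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.31, "shore": 0.23, "shelf": 0.10, "open_sea": 0.36}
    )
    flag_rates: Mapping[str, float] = field(
        default_factory=lambda: {"cross_reactive": 0.015, "snp_maf_gt_5pct": 0.02}
    )
    sex_chrom_fraction: float = 0.02
    hazard_by_tier: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.002, "intermediate": 0.01, "high": 0.03}
    )
    pp_event_mean_months: float = 24.0
    censoring_months: float = 120.0
    seed: int = 450

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {g} must be positive")
        for name, props in (
            ("annotation_proportions", self.annotation_proportions),
            ("island_proportions", self.island_proportions),
        ):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if any(h < 0 for h in self.hazard_by_tier.values()):
            raise ValueError("hazards must be non-negative")
        if self.censoring_months <= 0:
            raise ValueError("censoring_months must be positive (event times are > 0)")
        n_gp = self.outcome_split["GP_PTC"] + self.outcome_split["GP_FTC"]
        n_pp = self.outcome_split["PP_PTC"] + self.outcome_split["PP_FTC"]
        if self.outcome_split["GP_PTC"] + self.outcome_split["PP_PTC"] > self.group_sizes["PTC"]:
            raise ValueError("outcome split exceeds the number of PTC samples")
        if self.outcome_split["GP_FTC"] + self.outcome_split["PP_FTC"] > self.group_sizes["FTC_HCC"]:
            raise ValueError("outcome split exceeds the number of FTC/HCC samples")
        self.n_gp, self.n_pp = n_gp, n_pp


@dataclass
class SimulatedCohort:
    beta: BetaMatrix
    annotation: ProbeAnnotation
    qc: QCMetrics
    metadata: SampleMetadata
    survival: pd.DataFrame
    truth: pd.DataFrame


_HISTOLOGY_PLAN = {
    "NT": ("NT",),
    "BTL": ("FA", "goiter", "LT"),
    "PTC": ("PTC",),
    "FTC_HCC": ("FTC", "HCC"),
    "PDTC_ATC": ("PDTC", "ATC"),
}


def _make_metadata(config: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    rows = []
    for cls in ("NT", "BTL", "PTC", "FTC_HCC", "PDTC_ATC"):
        n = config.group_sizes[cls]
        histologies = _HISTOLOGY_PLAN[cls]
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{cls}_{i + 1:03d}",
                    "histology": histologies[i % len(histologies)],
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    df["outcome"] = "NA"
    for cls, histo_mask, gp_key, pp_key in (
        ("PTC", df["histology"] == "PTC", "GP_PTC", "PP_PTC"),
        ("FTC_HCC", df["histology"].isin(["FTC", "HCC"]), "GP_FTC", "PP_FTC"),
    ):
        ids = df.index[histo_mask].to_numpy()
        order = rng.permutation(len(ids))
        n_gp, n_pp = config.outcome_split[gp_key], config.outcome_split[pp_key]
        df.loc[ids[order[:n_gp]], "outcome"] = "GP"
        df.loc[ids[order[n_gp : n_gp + n_pp]], "outcome"] = "PP"
    df["multifocal"] = False
    # a couple of unlabelled WDTC samples carry multifocal primaries, so the
    # upstream exclusion rule has something to exclude
    na_wdtc = df.index[(df["outcome"] == "NA") & df["histology"].isin(["PTC", "FTC", "HCC"])]
    df.loc[na_wdtc[:2], "multifocal"] = True
    df["batch"] = [f"batch{1 + i % config.n_batches}" for i in range(len(df))]

    cap = config.censoring_months
    followup = rng.uniform(3.0, cap, size=len(df))
    event = np.zeros(len(df), dtype=bool)
    is_gp = (df["outcome"] == "GP").to_numpy()
    followup[is_gp] = rng.uniform(60.0, cap, size=is_gp.sum())
    is_pp = (df["outcome"] == "PP").to_numpy()
    t_event = rng.exponential(config.pp_event_mean_months, size=is_pp.sum())
    followup[is_pp] = np.minimum(t_event, cap - 1.0)
    event[is_pp] = True
    df["followup_months"] = np.maximum(followup, 0.5)
    df["recurrence_event"] = event
    return SampleMetadata(df)


def _make_annotation(config: SimulationConfig, rng: np.random.Generator) -> ProbeAnnotation:
    n = config.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    sex = rng.random(n) < config.sex_chrom_fraction
    chrom = np.where(sex, rng.choice(["X", "Y"], size=n, p=[0.85, 0.15]),
                     rng.integers(1, 23, size=n).astype(str))
    pos = rng.integers(10_000, 100_000_000, size=n)
    loc_names = list(config.annotation_proportions)
    loc = rng.choice(loc_names, size=n, p=[config.annotation_proportions[k] for k in loc_names])
    promoter_tokens = np.array(["TSS200", "TSS1500", "5UTR", "1stExon"])
    genes, regions = [], []
    for i in range(n):
        if loc[i] == "intergenic":
            genes.append(())
            regions.append(("intergenic",))
        else:
            gene = (f"GENE{i % 9000:05d}",)
            if loc[i] == "promoter":
                reg = (promoter_tokens[rng.integers(0, 4)],)
            else:
                reg = ("Body",) if rng.random() < 0.8 else ("3UTR",)
            # ~10% of genic probes carry a second gene association
            if rng.random() < 0.10:
                gene = gene + (f"GENE{(i + 17) % 9000:05d}",)
                reg = reg + ("Body",)
            genes.append(gene)
            regions.append(reg)
    isl_names = list(config.island_proportions)
    island = rng.choice(isl_names, size=n, p=[config.island_proportions[k] for k in isl_names])
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "genes": genes,
            "gene_regions": regions,
            "island_relation": island,
            "cross_reactive": rng.random(n) < config.flag_rates["cross_reactive"],
            "snp_maf_gt_5pct": rng.random(n) < config.flag_rates["snp_maf_gt_5pct"],
            "sex_chromosome": sex,
        },
        index=pd.Index(probe_ids, name="IlmnID"),
    )
    return ProbeAnnotation(table)


def _make_qc(
    config: SimulationConfig,
    probe_ids: pd.Index,
    sample_ids: pd.Index,
    rng: np.random.Generator,
) -> tuple[QCMetrics, np.ndarray]:
    n, s = len(probe_ids), len(sample_ids)
    n_fail = int(np.ceil(0.05 * s))
    detection = rng.uniform(0.0, 0.01, size=(n, s))
    beads = rng.poisson(11, size=(n, s)) + 3

    det_bad = rng.random(n) < config.qc_artifact_rates["detection_p"]
    bead_bad = rng.random(n) < config.qc_artifact_rates["bead_count"]
    for i in np.flatnonzero(det_bad):
        cols = rng.choice(s, size=min(s, n_fail + int(rng.integers(0, 3))), replace=False)
        detection[i, cols] = rng.uniform(0.06, 0.5, size=len(cols))
    for i in np.flatnonzero(bead_bad):
        cols = rng.choice(s, size=min(s, n_fail + int(rng.integers(0, 3))), replace=False)
        beads[i, cols] = rng.integers(0, 3, size=len(cols))
    qc = QCMetrics(
        detection_p=pd.DataFrame(detection, index=probe_ids, columns=sample_ids),
        bead_count=pd.DataFrame(beads, index=probe_ids, columns=sample_ids),
    )
    return qc, det_bad | bead_bad


def _calibrate_shift(logits: np.ndarray, target_mean: float) -> float:
    """Constant logit shift c with mean(expit(logits + c)) == target_mean."""
    f = lambda c: float(np.mean(expit(logits + c))) - target_mean
    return brentq(f, -36.0, 36.0, xtol=1e-12)


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate one cohort; identical config (incl. seed) gives identical output."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    metadata = _make_metadata(config, rng)
    annotation = _make_annotation(config, rng)
    probe_ids = annotation.probe_ids
    sample_ids = metadata.sample_ids
    qc, qc_bad = _make_qc(config, probe_ids, sample_ids, rng)

    n, s = config.n_probes, len(sample_ids)
    mode_betas = np.array([m for m, _ in config.beta_modes])
    mode_w = np.array([w for _, w in config.beta_modes])
    mode_w = mode_w / mode_w.sum()
    which = rng.choice(len(mode_betas), size=n, p=mode_w)
    mu = logit(mode_betas[which]) + rng.normal(0.0, config.probe_mean_sd, size=n)

    batch_idx = pd.Categorical(metadata.table["batch"]).codes
    batch_shift = rng.normal(0.0, config.batch_effect_sd, size=(n, config.n_batches))
    L = mu[:, None] + batch_shift[:, batch_idx] + rng.normal(0.0, config.sample_noise_sd, (n, s))

    # --- choose planted probes -------------------------------------------
    flagged = (
        annotation.table[["cross_reactive", "snp_maf_gt_5pct", "sex_chromosome"]]
        .any(axis=1)
        .to_numpy()
    )
    promoter = annotation.is_promoter().to_numpy()
    base_beta = expit(mu)
    taken = np.zeros(n, dtype=bool)

    def pick(count: int, delta: float, region: str | None, label: str) -> np.ndarray:
        # margin covers the gap between the expected baseline and the
        # realized reference-group mean (sampling noise + batch shift)
        lo = 0.08 + max(0.0, -delta)
        hi = 0.92 - max(0.0, delta)
        ok = ~flagged & ~qc_bad & ~taken & (base_beta > lo) & (base_beta < hi)
        if region == "promoter":
            ok &= promoter
        idx = np.flatnonzero(ok)
        if len(idx) < count:
            raise ValueError(
                f"cannot plant {count} probes for {label} at delta {delta:+.3f}: "
                f"only {len(idx)} eligible probes (baseline too extreme or budget exhausted)"
            )
        chosen = rng.choice(idx, size=count, replace=False)
        taken[chosen] = True
        return chosen

    plan: list[tuple[np.ndarray, str, str, float, bool]] = []
    if config.pp_panel is not None:
        panel = config.pp_panel
        signs = np.array([+1.0] * panel.n_hyper + [-1.0] * (panel.n_probes - panel.n_hyper))
        for sign in (+1.0, -1.0):
            count = int(np.sum(signs == sign))
            if count == 0:
                continue
            idx = pick(count, sign * panel.pdtc_delta, "promoter", "PP panel")
            plan.append((idx, "PDTC_ATC", "NT", sign * panel.pdtc_delta, True))
            plan.append((idx, "WDTC_PP", "WDTC_GP", sign * panel.pp_delta, True))
    for eff in config.planted_effects:
        idx = pick(eff.n_probes, eff.delta_beta, eff.region, eff.target)
        plan.append((idx, eff.target, eff.reference, eff.delta_beta, False))

    # --- calibrate realized shifts ---------------------------------------
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    beta = expit(L)
    truth_rows = []
    for idx, target, reference, delta, in_panel in plan:
        tgt_cols = np.array([col_of[sid] for sid in metadata.resolve_group(target)])
        ref_cols = np.array([col_of[sid] for sid in metadata.resolve_group(reference)])
        if len(tgt_cols) == 0 or len(ref_cols) == 0:
            raise ValueError(f"planted effect {target} vs {reference}: empty group")
        for i in idx:
            ref_mean = float(beta[i, ref_cols].mean())
            target_mean = ref_mean + delta
            if not (0.0 < target_mean < 1.0):
                raise ValueError(
                    f"unreachable delta-beta {delta:+.3f} for probe {probe_ids[i]!r}: "
                    f"reference mean {ref_mean:.3f} leaves no room in [0, 1]"
                )
            c = _calibrate_shift(L[i, tgt_cols], target_mean)
            beta[i, tgt_cols] = expit(L[i, tgt_cols] + c)
            truth_rows.append(
                {
                    "probe_id": probe_ids[i],
                    "target": target,
                    "reference": reference,
                    "delta_target": delta,
                    "direction": "hyper" if delta > 0 else "hypo",
                    "in_pp_panel": in_panel,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["probe_id", "target", "reference", "delta_target", "direction", "in_pp_panel"],
    )
    beta_m = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=sample_ids))

    meta_t = metadata.table
    wdtc = meta_t.index[meta_t["outcome"].isin(["GP", "PP"])]
    survival = pd.DataFrame(
        {
            "time_months": meta_t.loc[wdtc, "followup_months"],
            "event": meta_t.loc[wdtc, "recurrence_event"],
        }
    )
    survival.index.name = "sample_id"
    return SimulatedCohort(beta_m, annotation, qc, metadata, survival, truth)


def simulate_survival(
    metadata: SampleMetadata,
    tier_assignment: Mapping[str, str],
    config: SimulationConfig,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential recurrence times with tier-specific monthly hazards.

    Times are censored at ``config.censoring_months``; ``event`` is False
    when censored.  A zero hazard censors every sample of that tier.
    """
    for tier, h in config.hazard_by_tier.items():
        if h < 0:
            raise ValueError(f"hazard for tier {tier!r} must be non-negative")
    if config.censoring_months <= 0:
        raise ValueError("censoring time must be positive (survival times are > 0)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for sid in metadata.sample_ids:
        if sid not in tier_assignment:
            continue
        tier = tier_assignment[sid]
        h = config.hazard_by_tier[tier]
        if h == 0:
            t, ev = config.censoring_months, False
        else:
            draw = rng.exponential(1.0 / h)
            t, ev = min(draw, config.censoring_months), draw <= config.censoring_months
        rows.append({"sample_id": sid, "time_months": t, "event": ev})
    out = pd.DataFrame(rows, columns=["sample_id", "time_months", "event"]).set_index("sample_id")
    return out
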