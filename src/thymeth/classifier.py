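"""Prognostic DLDA classifier for well-differentiated thyroid carcinoma.

The signature is built by a two-stage probe cascade and scored by diagonal
linear discriminant analysis (DLDA):

1. *candidate selection* — probes differentially methylated between
   undifferentiated tumours (PDTC/ATC) and normal thyroid (|delta-beta| >
   0.2, Bonferroni-adjusted p < 0.05) and annotated to a promoter region
   (TSS200 / TSS1500 / 5'UTR / first exon) for at least one gene;
2. *prognostic filter* — candidates whose shift between poor- and
   good-prognosis well-differentiated cases (|delta-beta(PP - GP)| > 0.1)
   is sign-concordant with the undifferentiated shift and is specific to PP
   (good-prognosis cases stay within 0.1 of both normal tissue and benign
   lesions).

The retained probes train a DLDA — a diagonal-covariance Gaussian linear
classifier — whose score D(x) = sum_j w_j (x_j - m_j), with
w_j = (mu_PP_j - mu_GP_j) / s_j^2 (pooled within-class variance) and
midpoint m_j, classifies a sample as poor-prognosis when D(x) > 0 (equal
priors).  Samples are stratified into risk tiers: low (score within the
normal-tissue range), intermediate (above it but at or below the decision
threshold), high (above the threshold).

`PrognosticDLDA` / `PrognosticDLDAResults` expose the model in the usual
fit/results idiom; the module-level functions are the individual pipeline
operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    ProbeAnnotation,
    SampleMetadata,
    SignatureModel,
    PROMOTER_REGIONS,
)
from .diffmeth import ContrastSpec, call_differential, delta_beta

__all__ = [
    "CascadeConfig",
    "select_candidates",
    "prognostic_filter",
    "train_dlda",
    "score_samples",
    "stratify",
    "loocv",
    "LOOCVResult",
    "apply_fixed_signature",
    "load_reference_panel",
    "PrognosticDLDA",
    "PrognosticDLDAResults",
]

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """Thresholds and group roles of the two-stage probe cascade."""

    promoter_regions: frozenset = field(default_factory=lambda: frozenset(PROMOTER_REGIONS))
    stage1_contrast: ContrastSpec = field(
        default_factory=lambda: ContrastSpec("PDTC_ATC", "NT", delta_threshold=0.2, p_threshold=0.05)
    )
    stage2_delta: float = 0.1
    exclusivity_controls: tuple[str, ...] = ("NT", "BTL")
    require_sign_concordance: bool = True

    def __post_init__(self) -> None:
        if self.stage2_delta <= 0:
            raise ValueError("stage2_delta must be positive")


def select_candidates(diff_pdtc_atc: pd.DataFrame, ann: ProbeAnnotation,
                      promoter_regions: frozenset = frozenset(PROMOTER_REGIONS)) -> list[str]:
    """Differential stage-1 probes annotated to >=1 promoter region."""
    differential = diff_pdtc_atc.index[diff_pdtc_atc["direction"] != "none"]
    missing = differential.difference(ann.probe_ids)
    if len(missing):
        raise ValueError(f"annotations missing for probes: {missing.tolist()[:10]}")
    sub = ann.subset(differential).table
    keep = sub["gene_regions"].map(lambda regions: any(r in promoter_regions for r in regions))
    return differential[keep.to_numpy()].tolist()


def prognostic_filter(
    candidates: list[str],
    beta: BetaMatrix,
    metadata: SampleMetadata,
    config: CascadeConfig | None = None,
    *,
    samples_pp: list[str] | None = None,
    samples_gp: list[str] | None = None,
) -> list[str]:
    """Stage-2 filter: keep candidates exclusively altered in WDTC-PP.

    A candidate survives when |delta(PP - GP)| > stage2_delta, the sign of
    that shift matches the sign of the stage-1 undifferentiated shift
    (PDTC/ATC - NT), and the good-prognosis group stays within stage2_delta
    of every exclusivity control (NT, BTL) — i.e. the alteration is
    specific to poor prognosis, not a pan-tumour shift.
    """
    config = config or CascadeConfig()
    if not candidates:
        return []
    pp = samples_pp if samples_pp is not None else metadata.resolve_group("WDTC_PP")
    gp = samples_gp if samples_gp is not None else metadata.resolve_group("WDTC_GP")
    controls = {c: metadata.resolve_group(c) for c in config.exclusivity_controls}
    for name, members in [("WDTC_PP", pp), ("WDTC_GP", gp), *controls.items()]:
        if not members:
            raise ValueError(f"required sample group {name!r} is empty")
    sub = beta.subset(probes=candidates)
    d_pp_gp = delta_beta(sub, pp, gp)
    keep = d_pp_gp.abs() > config.stage2_delta
    if config.require_sign_concordance:
        s1 = config.stage1_contrast
        d_stage1 = delta_beta(
            sub, metadata.resolve_group(s1.group_a), metadata.resolve_group(s1.group_b)
        )
        keep &= np.sign(d_pp_gp) == np.sign(d_stage1)
    for members in controls.values():
        keep &= delta_beta(sub, gp, members).abs() <= config.stage2_delta
    return [p for p in candidates if keep[p]]


def train_dlda(
    beta: BetaMatrix,
    labels: pd.Series,
    *,
    nt_samples: list[str] | None = None,
    decision_threshold: float = 0.0,
    var_floor: float = 1e-6,
) -> SignatureModel:
    """Fit the diagonal LDA on the signature probes.

    ``labels`` maps sample id -> 'GP'/'PP' for the training samples; the
    matrix is restricted to those samples.  Missing beta values are imputed
    with the per-probe class mean (logged).  The pooled within-class
    variance is floored at ``var_floor`` (beta^2 units).  When NT samples
    are supplied, the model records the [min, max] of their scores as the
    low-risk band.
    """
    labels = labels.astype(str)
    bad = set(labels.unique()) - {"GP", "PP"}
    if bad:
        raise ValueError(f"labels must be GP/PP, got extra {sorted(bad)}")
    gp_ids = labels.index[labels == "GP"].tolist()
    pp_ids = labels.index[labels == "PP"].tolist()
    if len(gp_ids) < 2 or len(pp_ids) < 2:
        raise ValueError("need >=2 samples per class to train the DLDA")
    X = beta.subset(samples=labels.index.tolist()).values
    if X.isna().any().any():
        logger.info("imputing missing signature betas with per-probe class means")
        for ids in (gp_ids, pp_ids):
            block = X[ids]
            X[ids] = block.apply(lambda row: row.fillna(row.mean()), axis=1)
    xg = X[gp_ids].to_numpy()
    xp = X[pp_ids].to_numpy()
    mu_g, mu_p = xg.mean(axis=1), xp.mean(axis=1)
    ss = ((xg - mu_g[:, None]) ** 2).sum(axis=1) + ((xp - mu_p[:, None]) ** 2).sum(axis=1)
    raw_var = ss / (len(gp_ids) + len(pp_ids) - 2)
    if np.all(raw_var == 0):
        raise ValueError("zero within-class variance on every probe; cannot train DLDA")
    pooled = np.maximum(raw_var, var_floor)
    weights = (mu_p - mu_g) / pooled
    degenerate = bool(np.all(weights == 0))
    if degenerate:
        logger.warning("degenerate DLDA: identical class means on every probe (all weights 0)")
    model = SignatureModel(
        probe_ids=tuple(X.index),
        weights=weights,
        mean_gp=mu_g,
        mean_pp=mu_p,
        pooled_var=pooled,
        decision_threshold=decision_threshold,
        nt_score_range=None,
        degenerate=degenerate,
    )
    if nt_samples:
        nt_scores = score_samples(model, beta.subset(samples=nt_samples))["score"]
        model = SignatureModel(
            probe_ids=model.probe_ids,
            weights=model.weights,
            mean_gp=model.mean_gp,
            mean_pp=model.mean_pp,
            pooled_var=model.pooled_var,
            decision_threshold=decision_threshold,
            nt_score_range=(float(nt_scores.min()), float(nt_scores.max())),
            degenerate=degenerate,
        )
    return model


def score_samples(model: SignatureModel, beta: BetaMatrix) -> pd.DataFrame:
    """DLDA decision score per sample; higher = more PP-like."""
    missing = pd.Index(model.probe_ids).difference(beta.probe_ids)
    if len(missing):
        raise KeyError(f"signature probes missing from matrix: {missing.tolist()}")
    X = beta.subset(probes=list(model.probe_ids)).values.to_numpy()
    scores = model.weights @ (X - model.midpoints[:, None])
    return pd.DataFrame({"score": scores}, index=beta.sample_ids)


def stratify(model: SignatureModel, calls: pd.DataFrame) -> pd.DataFrame:
    """Assign risk tiers to scored samples.

    low: score <= upper end of the NT score range; intermediate: above it
    but <= decision threshold (ties go down); high: above the threshold.
    """
    if model.nt_score_range is None:
        raise ValueError("model carries no NT score range; cannot stratify")
    _, nt_hi = model.nt_score_range
    s = calls["score"]
    tier = np.where(s <= nt_hi, "low", np.where(s <= model.decision_threshold, "intermediate", "high"))
    out = calls.copy()
    out["tier"] = tier
    return out


def _confusion(true_pp: np.ndarray, pred_pp: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(true_pp & pred_pp))
    fn = int(np.sum(true_pp & ~pred_pp))
    tn = int(np.sum(~true_pp & ~pred_pp))
    fp = int(np.sum(~true_pp & pred_pp))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec


@dataclass
class LOOCVResult:
    calls: pd.DataFrame  # sample_id index, columns: true, predicted, score
    sensitivity: float
    specificity: float
    flagged: list[str]
    mode: str


def loocv(
    beta: BetaMatrix,
    metadata: SampleMetadata,
    config: CascadeConfig | None = None,
    mode: str = "full_cascade",
    *,
    annotation: ProbeAnnotation | None = None,
    probes: list[str] | None = None,
    n_tests: int | None = None,
) -> LOOCVResult:
    """Leave-one-out cross-validation of the prognostic classifier.

    ``full_cascade`` repeats the stage-2 prognostic filter and DLDA fit
    with each WDTC sample held out (stage 1 contrasts undifferentiated
    tumours with normal tissue, so it is unaffected by holding out a WDTC
    sample and is computed once); ``fixed_probes`` refits the DLDA on the
    supplied probe list only.  Entirely deterministic.
    """
    config = config or CascadeConfig()
    if mode not in ("full_cascade", "fixed_probes"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")
    pp = metadata.resolve_group("WDTC_PP")
    gp = metadata.resolve_group("WDTC_GP")
    if mode == "full_cascade":
        if annotation is None:
            raise ValueError("full_cascade LOOCV needs the probe annotation")
        diff1 = call_differential(config.stage1_contrast, beta, metadata, n_tests=n_tests)
        candidates = select_candidates(diff1, annotation, config.promoter_regions)
    elif probes is None:
        raise ValueError("fixed_probes LOOCV needs a probe list")

    rows, flagged = [], []
    for held in [*gp, *pp]:
        train_pp = [s for s in pp if s != held]
        train_gp = [s for s in gp if s != held]
        if not train_pp or not train_gp:
            flagged.append(held)
            continue
        if mode == "full_cascade":
            fold_probes = prognostic_filter(
                candidates, beta, metadata, config, samples_pp=train_pp, samples_gp=train_gp
            )
        else:
            fold_probes = list(probes)
        if not fold_probes:
            flagged.append(held)
            continue
        labels = pd.Series(
            ["GP"] * len(train_gp) + ["PP"] * len(train_pp), index=train_gp + train_pp
        )
        try:
            model = train_dlda(beta.subset(probes=fold_probes), labels)
        except ValueError:
            # a fold whose training classes are too small/degenerate is
            # excluded and reported rather than aborting the whole CV
            flagged.append(held)
            continue
        score = float(score_samples(model, beta.subset(samples=[held]))["score"].iloc[0])
        rows.append(
            {
                "sample_id": held,
                "true": "PP" if held in pp else "GP",
                "predicted": "PP" if score > model.decision_threshold else "GP",
                "score": score,
            }
        )
    calls = pd.DataFrame(rows, columns=["sample_id", "true", "predicted", "score"])
    calls = calls.set_index("sample_id")
    if calls.empty:
        return LOOCVResult(calls, float("nan"), float("nan"), flagged, mode)
    sens, spec = _confusion(
        (calls["true"] == "PP").to_numpy(), (calls["predicted"] == "PP").to_numpy()
    )
    return LOOCVResult(calls, sens, spec, flagged, mode)


def apply_fixed_signature(
    model: SignatureModel,
    external_beta: BetaMatrix,
    external_metadata: SampleMetadata,
    *,
    min_gp_followup_months: float = 60.0,
) -> tuple[pd.DataFrame, float, float]:
    """Apply a trained signature to an external cohort without refitting.

    The training cohort's inclusion rules are re-applied: good prognosis
    requires event-free follow-up of at least ``min_gp_followup_months``
    (5 years); poor prognosis requires a confirmed recurrence and excludes
    multifocal primaries.  Returns (risk calls, sensitivity, specificity).
    """
    t = external_metadata.table
    wdtc = t["histology"].isin(["PTC", "FTC", "HCC"])
    is_pp = wdtc & t["recurrence_event"] & ~t["multifocal"]
    is_gp = wdtc & ~t["recurrence_event"] & (t["followup_months"] >= min_gp_followup_months)
    included = t.index[is_pp | is_gp].tolist()
    if not included:
        raise ValueError("no external samples satisfy the inclusion rules")
    calls = score_samples(model, external_beta.subset(samples=included))
    if model.nt_score_range is not None:
        calls = stratify(model, calls)
    # align truth with the score rows (subset keeps matrix column order)
    true_pp = is_pp.loc[calls.index].to_numpy()
    pred_pp = (calls["score"] > model.decision_threshold).to_numpy()
    sens, spec = _confusion(true_pp, pred_pp)
    return calls, sens, spec


def load_reference_panel() -> pd.DataFrame:
    """The published 21-probe prognostic panel.

    Columns: probe_id, gene, promoter_region, the two reported delta-beta
    columns (PDTC/ATC - NT and WDTC-PP - WDTC-GP) and the reported DLDA
    score (sign/relative magnitude reference only; the original tool's
    absolute scaling is not reproduced here).
    """
    with resources.files("thymeth.data").joinpath("prognostic_panel_21.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class PrognosticDLDA:
    """DLDA prognostic model for GP/PP outcome on a probe panel.

    Build directly from a beta matrix plus metadata and an explicit probe
    list, or let :meth:`from_cohort` run the candidate cascade to choose
    the panel.  :meth:`fit` returns a :class:`PrognosticDLDAResults`.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        metadata: SampleMetadata,
        probe_ids: list[str],
        *,
        config: CascadeConfig | None = None,
        use_nt_range: bool = True,
    ):
        if not probe_ids:
            raise ValueError("the signature probe list is empty")
        self.beta = beta
        self.metadata = metadata
        self.probe_ids = list(probe_ids)
        self.config = config or CascadeConfig()
        self.use_nt_range = use_nt_range
        self.cascade_info: dict = {}
        self._annotation: ProbeAnnotation | None = None

    @classmethod
    def from_cohort(
        cls,
        beta: BetaMatrix,
        annotation: ProbeAnnotation,
        metadata: SampleMetadata,
        config: CascadeConfig | None = None,
        *,
        n_tests: int | None = None,
    ) -> "PrognosticDLDA":
        """Run the two-stage cascade on a QC-filtered cohort."""
        config = config or CascadeConfig()
        diff1 = call_differential(config.stage1_contrast, beta, metadata, n_tests=n_tests)
        candidates = select_candidates(diff1, annotation, config.promoter_regions)
        signature = prognostic_filter(candidates, beta, metadata, config)
        if not signature:
            raise ValueError("the prognostic cascade retained no probes")
        obj = cls(beta, metadata, signature, config=config)
        obj._annotation = annotation
        obj.cascade_info = {
            "n_stage1_differential": int((diff1["direction"] != "none").sum()),
            "n_candidates": len(candidates),
            "n_signature": len(signature),
            "n_tests": diff1.attrs["n_tests"],
        }
        return obj

    def fit(self) -> "PrognosticDLDAResults":
        gp = self.metadata.resolve_group("WDTC_GP")
        pp = self.metadata.resolve_group("WDTC_PP")
        labels = pd.Series(["GP"] * len(gp) + ["PP"] * len(pp), index=gp + pp)
        nt = self.metadata.resolve_group("NT") if self.use_nt_range else None
        sig = train_dlda(
            self.beta.subset(probes=self.probe_ids), labels, nt_samples=nt or None
        )
        return PrognosticDLDAResults(self, sig, labels)


class PrognosticDLDAResults:
    """Fitted prognostic signature: estimates, scores, tiers, validation."""

    def __init__(self, model: PrognosticDLDA, signature: SignatureModel, labels: pd.Series):
        self.model = model
        self.signature = signature
        self.labels = labels

    @property
    def params(self) -> pd.Series:
        """Per-probe DLDA weights (beta^-1 units); sign tracks PP - GP."""
        return pd.Series(self.signature.weights, index=self.signature.probe_ids, name="weight")

    @property
    def probe_table(self) -> pd.DataFrame:
        s = self.signature
        return pd.DataFrame(
            {
                "weight": s.weights,
                "mean_gp": s.mean_gp,
                "mean_pp": s.mean_pp,
                "delta_pp_gp": s.mean_pp - s.mean_gp,
                "pooled_var": s.pooled_var,
            },
            index=pd.Index(s.probe_ids, name="probe_id"),
        )

    def score(self, beta: BetaMatrix | None = None) -> pd.DataFrame:
        return score_samples(self.signature, beta if beta is not None else self.model.beta)

    def stratify(self, beta: BetaMatrix | None = None) -> pd.DataFrame:
        return stratify(self.signature, self.score(beta))

    def predict(self, beta: BetaMatrix | None = None) -> pd.Series:
        calls = self.score(beta)
        return pd.Series(
            np.where(calls["score"] > self.signature.decision_threshold, "PP", "GP"),
            index=calls.index,
            name="predicted",
        )

    def resubstitution(self) -> tuple[float, float]:
        """Sensitivity/specificity of the fitted model on its training data."""
        pred = self.predict(self.model.beta.subset(samples=self.labels.index.tolist()))
        return _confusion(
            (self.labels == "PP").to_numpy(), (pred.loc[self.labels.index] == "PP").to_numpy()
        )

    def loocv(self, mode: str = "full_cascade") -> LOOCVResult:
        m = self.model
        if mode == "fixed_probes":
            return loocv(m.beta, m.metadata, m.config, mode, probes=m.probe_ids)
        if m._annotation is None:
            raise ValueError("full_cascade LOOCV requires a model built via from_cohort")
        return loocv(
            m.beta,
            m.metadata,
            m.config,
            mode,
            annotation=m._annotation,
            n_tests=m.cascade_info.get("n_tests"),
        )

    def apply(self, external_beta: BetaMatrix, external_metadata: SampleMetadata):
        """Fixed-weight application to an external cohort (no refitting)."""
        return apply_fixed_signature(self.signature, external_beta, external_metadata)

    def summary(self) -> str:
        s = self.signature
        sens, spec = self.resubstitution()
        n_pos = int(np.sum(s.weights > 0))
        n_neg = int(np.sum(s.weights < 0))
        lines = [
            "Prognostic DLDA signature",
            "=" * 60,
            f"probes: {len(s.probe_ids)}  ({n_pos} hypermethylated / {n_neg} hypomethylated in PP)",
            f"training samples: {int((self.labels == 'GP').sum())} GP, "
            f"{int((self.labels == 'PP').sum())} PP",
            f"decision threshold: {s.decision_threshold:.3f}",
        ]
        if s.nt_score_range is not None:
            lines.append(
                f"NT score range (low-risk band): [{s.nt_score_range[0]:.3f}, {s.nt_score_range[1]:.3f}]"
            )
        lines.append(f"resubstitution sensitivity/specificity: {sens:.2f} / {spec:.2f}")
        lines.append("-" * 60)
        tbl = self.probe_table.sort_values("weight")
        lines.append(f"{'probe_id':<14}{'weight':>10}{'mean_gp':>9}{'mean_pp':>9}{'delta':>8}")
        for pid, row in tbl.iterrows():
            lines.append(
                f"{pid:<14}{row['weight']:>10.2f}{row['mean_gp']:>9.3f}"
                f"{row['mean_pp']:>9.3f}{row['delta_pp_gp']:>8.3f}"
            )
        return "\n".join(lines)
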