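"""Core containers for 450k-style methylation analysis.

All tabular containers are thin, validated wrappers around pandas objects:
a :class:`BetaMatrix` (probes x samples, values in [0, 1]), per-probe
annotations in the style of the Illumina 450k manifest, per-probe/per-sample
QC metrics (detection p-value, bead count), and per-sample clinical metadata
(histology, outcome, follow-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "QCMetrics",
    "SampleMetadata",
    "SignatureModel",
    "HISTOLOGIES",
    "LESION_CLASSES",
    "GENE_REGIONS",
    "ISLAND_RELATIONS",
    "PROMOTER_REGIONS",
    "FLAG_COLUMNS",
    "derive_lesion_class",
]

HISTOLOGIES = ("NT", "FA", "goiter", "LT", "PTC", "FTC", "HCC", "PDTC", "ATC")
LESION_CLASSES = ("NT", "BTL", "PTC", "FTC_HCC", "PDTC_ATC")
GENE_REGIONS = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "intergenic")
PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500", "5UTR", "1stExon"})
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
FLAG_COLUMNS = ("cross_reactive", "snp_maf_gt_5pct", "sex_chromosome")

_LESION_CLASS_OF = {
    "NT": "NT",
    "FA": "BTL",
    "goiter": "BTL",
    "LT": "BTL",
    "PTC": "PTC",
    "FTC": "FTC_HCC",
    "HCC": "FTC_HCC",
    "PDTC": "PDTC_ATC",
    "ATC": "PDTC_ATC",
}

# histologies for which a GP/PP outcome label is meaningful (well-differentiated)
WDTC_HISTOLOGIES = frozenset({"PTC", "FTC", "HCC"})


def derive_lesion_class(histology: str) -> str:
    """Map a histology label onto its analysis lesion class."""
    try:
        return _LESION_CLASS_OF[histology]
    except KeyError:
        raise ValueError(
            f"unknown histology {histology!r}; expected one of {HISTOLOGIES}"
        ) from None


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


class BetaMatrix:
    """Probes x samples matrix of methylation beta fractions in [0, 1].

    Missing measurements are carried as NaN; every downstream per-probe
    statistic is pairwise-complete over the samples it uses.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("BetaMatrix expects a probes x samples DataFrame")
        values = values.astype(float)
        _check_unique(values.index, "probe ids")
        _check_unique(values.columns, "sample ids")
        arr = values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}: {arr[i, j]}"
            )
        self._values = values

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "BetaMatrix":
        return cls(pd.DataFrame(values, index=list(probe_ids), columns=list(sample_ids)))

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def probe_ids(self) -> pd.Index:
        return self._values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self._values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def subset(
        self,
        probes: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "BetaMatrix":
        """Restrict to the given probes/samples, preserving the stored order."""
        df = self._values
        if probes is not None:
            probes = pd.Index(probes)
            missing = probes.difference(df.index)
            if len(missing):
                raise KeyError(f"probes absent from matrix: {missing.tolist()[:10]}")
            df = df.loc[df.index.intersection(probes, sort=False)]
        if samples is not None:
            samples = pd.Index(samples)
            missing = samples.difference(df.columns)
            if len(missing):
                raise KeyError(f"samples absent from matrix: {missing.tolist()[:10]}")
            df = df.loc[:, df.columns.intersection(samples, sort=False)]
        out = BetaMatrix.__new__(BetaMatrix)
        out._values = df
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"<BetaMatrix {p} probes x {s} samples>"


class ProbeAnnotation:
    """Per-probe genomic context and QC flags.

    Backed by a DataFrame indexed by probe id with columns:

    ``chrom`` (manifest-style label), ``pos`` (1-based), ``genes`` (tuple of
    gene symbols), ``gene_regions`` (tuple of region tokens aligned with
    ``genes``, or ``("intergenic",)`` when no gene), ``island_relation``
    (island/shore/shelf/open_sea) and the three boolean flags
    ``cross_reactive``, ``snp_maf_gt_5pct``, ``sex_chromosome``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos", "genes", "gene_regions", "island_relation", *FLAG_COLUMNS}
        missing = required.difference(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        _check_unique(table.index, "probe ids")
        if (table["pos"] < 1).any():
            bad = table.index[table["pos"] < 1][0]
            raise ValueError(f"probe {bad!r} has position < 1")
        unknown_rel = set(table["island_relation"]) - set(ISLAND_RELATIONS)
        if unknown_rel:
            raise ValueError(f"unknown island relation tokens: {sorted(unknown_rel)}")
        for probe, genes, regions in zip(table.index, table["genes"], table["gene_regions"]):
            unknown = set(regions) - set(GENE_REGIONS)
            if unknown:
                raise ValueError(f"probe {probe!r}: unknown gene_region tokens {sorted(unknown)}")
            if (len(genes) == 0) != (regions == ("intergenic",)):
                raise ValueError(
                    f"probe {probe!r}: gene_region must be intergenic iff no gene is associated"
                )
        for col in FLAG_COLUMNS:
            if table[col].isna().any():
                raise ValueError(f"flag column {col!r} contains missing values")
        self._table = table.assign(**{c: table[c].astype(bool) for c in FLAG_COLUMNS})

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def probe_ids(self) -> pd.Index:
        return self._table.index

    def is_promoter(self) -> pd.Series:
        """True for probes annotated to >=1 promoter region (any associated gene)."""
        return self._table["gene_regions"].map(
            lambda regions: any(r in PROMOTER_REGIONS for r in regions)
        )

    def subset(self, probes: Iterable[str]) -> "ProbeAnnotation":
        probes = pd.Index(probes)
        missing = probes.difference(self._table.index)
        if len(missing):
            raise KeyError(f"probes absent from annotation: {missing.tolist()[:10]}")
        out = ProbeAnnotation.__new__(ProbeAnnotation)
        out._table = self._table.loc[probes]
        return out

    def __len__(self) -> int:
        return len(self._table)


@dataclass
class QCMetrics:
    """Detection p-values and bead counts aligned with a BetaMatrix."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        if self.detection_p.shape != self.bead_count.shape:
            raise ValueError("detection_p and bead_count shapes differ")
        if not self.detection_p.index.equals(self.bead_count.index) or not (
            self.detection_p.columns.equals(self.bead_count.columns)
        ):
            raise ValueError("detection_p and bead_count are not aligned")
        dp = self.detection_p.to_numpy()
        if np.any((dp < 0) | (dp > 1)):
            raise ValueError("detection p-values must lie in [0, 1]")
        if (self.bead_count.to_numpy() < 0).any():
            raise ValueError("bead counts must be non-negative")

    def check_aligned(self, beta: BetaMatrix) -> None:
        if not self.detection_p.index.equals(beta.probe_ids) or not (
            self.detection_p.columns.equals(beta.sample_ids)
        ):
            raise ValueError("QC metrics are not aligned with the beta matrix")


class SampleMetadata:
    """Per-sample clinical annotations.

    Indexed by sample id with columns ``histology``, ``lesion_class``
    (derived), ``outcome`` (GP/PP/NA), ``multifocal``, ``followup_months``,
    ``recurrence_event`` and ``batch``.
    """

    COLUMNS = (
        "histology",
        "lesion_class",
        "outcome",
        "multifocal",
        "followup_months",
        "recurrence_event",
        "batch",
    )

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        _check_unique(table.index, "sample ids")
        unknown = set(table["histology"]) - set(HISTOLOGIES)
        if unknown:
            raise ValueError(f"unknown histology labels: {sorted(unknown)}")
        derived = table["histology"].map(_LESION_CLASS_OF)
        if "lesion_class" in table.columns:
            clash = table.index[table["lesion_class"].astype(str) != derived]
            if len(clash):
                raise ValueError(
                    f"lesion_class disagrees with histology for samples {clash.tolist()[:5]}"
                )
        table["lesion_class"] = derived
        outcome = table["outcome"].fillna("NA").astype(str)
        bad_tokens = set(outcome) - {"GP", "PP", "NA"}
        if bad_tokens:
            raise ValueError(f"unknown outcome labels: {sorted(bad_tokens)}")
        non_wdtc = ~table["histology"].isin(WDTC_HISTOLOGIES)
        offenders = table.index[non_wdtc & (outcome != "NA")]
        if len(offenders):
            raise ValueError(
                "outcome labels are only meaningful for well-differentiated carcinoma "
                f"(PTC/FTC/HCC); offending samples: {offenders.tolist()[:5]}"
            )
        table["outcome"] = outcome
        if (table["followup_months"] < 0).any():
            raise ValueError("followup_months must be non-negative")
        table["multifocal"] = table["multifocal"].astype(bool)
        table["recurrence_event"] = table["recurrence_event"].astype(bool)
        self._table = table[list(self.COLUMNS)]

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def sample_ids(self) -> pd.Index:
        return self._table.index

    def samples_in_class(self, lesion_class: str) -> list[str]:
        if lesion_class not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {lesion_class!r}")
        t = self._table
        return t.index[t["lesion_class"] == lesion_class].tolist()

    def samples_with_outcome(self, outcome: str, exclude_multifocal_pp: bool = False) -> list[str]:
        t = self._table
        mask = t["outcome"] == outcome
        if exclude_multifocal_pp and outcome == "PP":
            mask &= ~t["multifocal"]
        return t.index[mask].tolist()

    def resolve_group(self, label: str, exclude_multifocal_pp: bool = True) -> list[str]:
        """Resolve a lesion class or outcome-group label to sample ids.

        Accepts lesion classes (NT, BTL, ...) and the outcome groups
        ``WDTC_GP`` / ``WDTC_PP`` (multifocal poor-prognosis primaries are
        excluded from WDTC_PP by default, matching the classifier's
        inclusion rules).
        """
        if label in LESION_CLASSES:
            return self.samples_in_class(label)
        if label in ("WDTC_GP", "GP"):
            return self.samples_with_outcome("GP")
        if label in ("WDTC_PP", "PP"):
            return self.samples_with_outcome("PP", exclude_multifocal_pp=exclude_multifocal_pp)
        raise ValueError(f"cannot resolve sample group {label!r}")

    def __len__(self) -> int:
        return len(self._table)


@dataclass
class SignatureModel:
    """A trained diagonal linear discriminant signature.

    The decision score of a sample x is ``D(x) = sum_j w_j (x_j - m_j)``
    with ``w_j = (mu_PP_j - mu_GP_j) / s2_j`` and midpoint
    ``m_j = (mu_GP_j + mu_PP_j) / 2``; higher scores are more PP-like.
    Risk tiers: low (within the score range of normal tissue), intermediate
    (above that range but at or below the decision threshold), high (above
    the threshold).
    """

    probe_ids: tuple[str, ...]
    weights: np.ndarray
    mean_gp: np.ndarray
    mean_pp: np.ndarray
    pooled_var: np.ndarray
    decision_threshold: float = 0.0
    nt_score_range: tuple[float, float] | None = None
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        for name in ("weights", "mean_gp", "mean_pp", "pooled_var"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if len(set(self.probe_ids)) != n:
            raise ValueError("signature probe ids must be unique")
        diff = self.mean_pp - self.mean_gp
        if np.any(np.sign(self.weights) != np.sign(diff)):
            raise ValueError("weight signs must match sign(mean_pp - mean_gp)")
        if self.nt_score_range is not None:
            lo, hi = self.nt_score_range
            if lo > hi:
                raise ValueError("nt_score_range must satisfy lo <= hi")
            if hi > self.decision_threshold:
                raise ValueError(
                    "incoherent stratification: NT score range exceeds the decision "
                    f"threshold (NT max {hi:.4g} > threshold {self.decision_threshold:.4g})"
                )

    @property
    def midpoints(self) -> np.ndarray:
        return (self.mean_gp + self.mean_pp) / 2.0

    def to_json(self, path=None) -> str:
        payload = {
            "probes": [
                {
                    "probe_id": p,
                    "weight": float(w),
                    "mean_gp": float(g),
                    "mean_pp": float(q),
                    "pooled_var": float(v),
                }
                for p, w, g, q, v in zip(
                    self.probe_ids, self.weights, self.mean_gp, self.mean_pp, self.pooled_var
                )
            ],
            "decision_threshold": float(self.decision_threshold),
            "nt_score_range": list(self.nt_score_range) if self.nt_score_range else None,
            "degenerate": bool(self.degenerate),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SignatureModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text, encoding="utf-8") as fh:
                    payload = json.load(fh)
        probes = payload["probes"]
        rng = payload.get("nt_score_range")
        return cls(
            probe_ids=tuple(p["probe_id"] for p in probes),
            weights=np.array([p["weight"] for p in probes]),
            mean_gp=np.array([p["mean_gp"] for p in probes]),
            mean_pp=np.array([p["mean_pp"] for p in probes]),
            pooled_var=np.array([p["pooled_var"] for p in probes]),
            decision_threshold=float(payload["decision_threshold"]),
            nt_score_range=tuple(rng) if rng else None,
            degenerate=bool(payload.get("degenerate", False)),
        )
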