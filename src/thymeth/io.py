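"""Readers and writers for the three tabular interchange formats.

* beta matrix — TSV, probes as rows, header row of sample ids, missing
  values written as ``NA``;
* probe manifest — TSV with Illumina-450k-manifest column names
  (``IlmnID``, ``CHR``, ``MAPINFO``, ``UCSC_RefGene_Name``,
  ``UCSC_RefGene_Group``, ``Relation_to_UCSC_CpG_Island`` plus flag
  columns);
* sample sheet — CSV.

All files are UTF-8 with '.' as decimal separator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    FLAG_COLUMNS,
    GENE_REGIONS,
    BetaMatrix,
    ProbeAnnotation,
    QCMetrics,
    SampleMetadata,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_qc_metrics",
    "write_qc_metrics",
]

_MANIFEST_REGION_TOKENS = {
    "TSS200": "TSS200",
    "TSS1500": "TSS1500",
    "5'UTR": "5UTR",
    "5UTR": "5UTR",
    "1stExon": "1stExon",
    "1st exon": "1stExon",
    "Body": "Body",
    "3'UTR": "3UTR",
    "3UTR": "3UTR",
}

_ISLAND_TOKENS = {
    "Island": "island",
    "N_Shore": "shore",
    "S_Shore": "shore",
    "N_Shelf": "shelf",
    "S_Shelf": "shelf",
    "": "open_sea",
    "OpenSea": "open_sea",
}

_REGION_TO_MANIFEST = {"5UTR": "5'UTR", "3UTR": "3'UTR"}


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples TSV of beta values; ``NA`` marks missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.name is None or df.shape[1] == 0:
        raise ValueError(f"{path}: malformed header (need a probe-id column and >=1 sample)")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric beta value ({exc})") from None
    try:
        return BetaMatrix(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def _parse_manifest_row(probe: str, row: pd.Series) -> dict:
    genes_raw = str(row.get("UCSC_RefGene_Name", "") or "")
    regions_raw = str(row.get("UCSC_RefGene_Group", "") or "")
    genes = tuple(g for g in genes_raw.split(";") if g)
    regions = []
    for token in (t for t in regions_raw.split(";") if t):
        if token not in _MANIFEST_REGION_TOKENS:
            raise ValueError(
                f"probe {probe!r}: unknown gene_region token {token!r} "
                f"(expected one of {sorted(set(_MANIFEST_REGION_TOKENS))})"
            )
        regions.append(_MANIFEST_REGION_TOKENS[token])
    if genes and len(regions) != len(genes):
        raise ValueError(
            f"probe {probe!r}: {len(genes)} genes but {len(regions)} region tokens"
        )
    if not genes:
        regions = ["intergenic"]
    island_raw = str(row.get("Relation_to_UCSC_CpG_Island", "") or "")
    if island_raw not in _ISLAND_TOKENS:
        raise ValueError(f"probe {probe!r}: unknown island relation {island_raw!r}")
    return {
        "chrom": str(row["CHR"]),
        "pos": int(row["MAPINFO"]),
        "genes": genes,
        "gene_regions": tuple(regions),
        "island_relation": _ISLAND_TOKENS[island_raw],
        "cross_reactive": bool(int(row["cross_reactive"])),
        "snp_maf_gt_5pct": bool(int(row["snp_maf_gt_5pct"])),
        "sex_chromosome": bool(int(row["sex_chromosome"])),
    }


def read_manifest(path) -> ProbeAnnotation:
    """Read a probe manifest TSV with Illumina-style columns.

    Multi-gene fields are split on ';'; island relations are normalised
    (N_Shore/S_Shore -> shore, N_Shelf/S_Shelf -> shelf, empty -> open_sea).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    required = {
        "IlmnID",
        "CHR",
        "MAPINFO",
        "UCSC_RefGene_Name",
        "UCSC_RefGene_Group",
        "Relation_to_UCSC_CpG_Island",
        *FLAG_COLUMNS,
    }
    missing = required.difference(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records = {}
    for _, row in df.iterrows():
        probe = row["IlmnID"]
        records[probe] = _parse_manifest_row(probe, row)
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "IlmnID"
    return ProbeAnnotation(table)


def write_manifest(ann: ProbeAnnotation, path) -> None:
    t = ann.table
    out = pd.DataFrame(index=t.index)
    out["IlmnID"] = t.index
    out["CHR"] = t["chrom"]
    out["MAPINFO"] = t["pos"]
    out["UCSC_RefGene_Name"] = t["genes"].map(";".join)
    out["UCSC_RefGene_Group"] = [
        ";".join(_REGION_TO_MANIFEST.get(r, r) for r in regions) if genes else ""
        for genes, regions in zip(t["genes"], t["gene_regions"])
    ]
    out["Relation_to_UCSC_CpG_Island"] = t["island_relation"].map(
        {"island": "Island", "shore": "N_Shore", "shelf": "N_Shelf", "open_sea": ""}
    )
    for col in FLAG_COLUMNS:
        out[col] = t[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleMetadata:
    """Read a sample sheet CSV; lesion_class is derived from histology."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=False)
    required = {"histology", "outcome", "multifocal", "followup_months", "recurrence_event", "batch"}
    missing = required.difference(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["multifocal"] = df["multifocal"].astype(int).astype(bool)
    df["recurrence_event"] = df["recurrence_event"].astype(int).astype(bool)
    try:
        return SampleMetadata(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_sample_sheet(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out["multifocal"] = out["multifocal"].astype(int)
    out["recurrence_event"] = out["recurrence_event"].astype(int)
    out.to_csv(path, index_label="sample_id", na_rep="NA")


def read_qc_metrics(detection_path, bead_path) -> QCMetrics:
    dp = pd.read_csv(detection_path, sep="\t", index_col=0).astype(float)
    bc = pd.read_csv(bead_path, sep="\t", index_col=0).astype(int)
    return QCMetrics(detection_p=dp, bead_count=bc)


def write_qc_metrics(qc: QCMetrics, detection_path, bead_path) -> None:
    qc.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")
    qc.bead_count.to_csv(bead_path, sep="\t", index_label="probe_id")
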