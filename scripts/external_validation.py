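#!/usr/bin/env python
"""Apply a trained prognostic signature to a user-downloaded external cohort.

This script is for users who have obtained real 450k data themselves — e.g.
a processed beta-value matrix exported from a GEO series or TCGA level-3
thyroid-carcinoma methylation tables — and want to evaluate a fixed,
previously trained signature on it without any refitting.

Expected inputs (see the package README for the formats):

* ``--model``   signature JSON written by ``thymeth build-signature``;
* ``--beta``    TSV beta matrix (probes x samples) containing at least the
  signature probes;
* ``--samples`` CSV sample sheet with histology, multifocal,
  followup_months and recurrence_event columns.

The cohort inclusion rules of the training design are re-applied: good
prognosis requires >= 5 years of event-free follow-up; poor prognosis
requires a confirmed recurrence and excludes multifocal primary tumours.

Usage:
    python scripts/external_validation.py --model model.json \
        --beta external_beta.tsv --samples external_samples.csv \
        --out external_metrics.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from thymeth.classifier import apply_fixed_signature
from thymeth.datatypes import SignatureModel
from thymeth.io import read_beta_matrix, read_sample_sheet


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", type=Path, required=True)
    ap.add_argument("--beta", type=Path, required=True)
    ap.add_argument("--samples", type=Path, required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--min-gp-followup-months", type=float, default=60.0)
    args = ap.parse_args()

    model = SignatureModel.from_json(args.model)
    beta = read_beta_matrix(args.beta)
    metadata = read_sample_sheet(args.samples)
    calls, sensitivity, specificity = apply_fixed_signature(
        model, beta, metadata, min_gp_followup_months=args.min_gp_followup_months
    )
    payload = {
        "n_samples_included": int(len(calls)),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "tier_counts": (
            calls["tier"].value_counts().to_dict() if "tier" in calls else None
        ),
    }
    with open(args.out, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    calls.to_csv(args.out.with_suffix(".calls.csv"), index_label="sample_id")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
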