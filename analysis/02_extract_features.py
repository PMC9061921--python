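#!/usr/bin/env python
"""Extract the 157-feature radiomics table for both mask provenances.

Reads the cohort written by 01_simulate_cohort.py, applies outlier
re-segmentation (1st-99th percentile) and 64-bin discretization per modality,
and computes the 2.5D slice-averaged texture catalogue plus ROI volume and
the four ADC first-order statistics.  One CSV per provenance under results/.
"""

import argparse
import os

from rectomics.imaging import load_cohort
from rectomics.pipeline import PipelineConfig, build_feature_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="scratch/cohort/clinical.csv")
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    cases = load_cohort(args.cohort)
    cfg = PipelineConfig()
    os.makedirs(args.out_dir, exist_ok=True)
    for provenance in ("manual", "automatic"):
        table = build_feature_table(cases, provenance, cfg)
        path = os.path.join(args.out_dir, f"features_{provenance}.csv")
        table.to_csv(path, index=False)
        print(f"{provenance}: {table.shape[0]} cases x {table.shape[1] - 6} features -> {path}")


if __name__ == "__main__":
    main()
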