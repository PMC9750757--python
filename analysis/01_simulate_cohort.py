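"""Simulate the study cohort: 150 trauma patients (38 early non-survivors,
34 resolvers, 78 non-resolvers) plus 29 low-ISS controls, measured on a
184-analyte immune panel at 0/24/72 h (ENS and controls at 0 h only).

Writes the expression matrix, sample metadata, manifest, ground-truth
ledger and config under results/cohort/.
"""

import argparse

import pandas as pd

from traumapanel import GeneratorConfig, write_fixture


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", default="results/cohort")
    args = parser.parse_args()

    paths = write_fixture(args.out, GeneratorConfig(seed=args.seed))
    meta = pd.read_csv(paths["metadata"])
    pats = meta.drop_duplicates("patient_id")
    print(f"wrote cohort to {args.out} (seed {args.seed})")
    print("patients per group:")
    print(pats["group"].value_counts().to_string())
    print("samples per group x timepoint:")
    print(meta.groupby(["group", "timepoint"]).size().to_string())
    matrix = pd.read_csv(paths["matrix"], sep="\t", index_col=0)
    print(f"matrix: {matrix.shape[0]} analytes x {matrix.shape[1]} samples, "
          f"{matrix.isna().to_numpy().mean():.1%} missing")


if __name__ == "__main__":
    main()
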