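"""Outcome- and severity-stratified differential statistics.

Builds the heatmap z-score matrices (per outcome group and per ISS stratum),
the NR-vs-R volcano tables at 24 and 72 h, and the cohort demographics
summary with between-group tests.  Writes tables under results/differential/.
"""

import argparse
from pathlib import Path

import pandas as pd

from traumapanel import (
    cohort_summary,
    iss_stratum,
    preprocess_panel,
    read_expression,
    volcano_table,
    zscore_matrix,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--out", default="results/differential")
    args = parser.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = Path(args.cohort)

    matrix, manifest, meta = read_expression(
        cohort / "expression.tsv", cohort / "sample_metadata.csv",
        cohort / "manifest.csv",
    )
    log2m, _ = preprocess_panel(matrix, manifest, roles=("mediator",))

    def outcome_grouping(sid):
        return meta.loc[sid, "group"], meta.loc[sid, "timepoint"]

    heat = zscore_matrix(log2m, outcome_grouping)
    heat.z.rename_axis("analyte_id").to_csv(outdir / "heatmap_outcome.tsv",
                                            sep="\t")
    print(f"outcome heatmap: {heat.z.shape[0]} mediators x "
          f"{heat.z.shape[1]} (group, time) cells")

    def severity_grouping(sid):
        row = meta.loc[sid]
        if row["group"] == "CONTROL":
            return "control", row["timepoint"]
        return iss_stratum(int(row["iss"])), row["timepoint"]

    heat_iss = zscore_matrix(log2m, severity_grouping, compare=None)
    heat_iss.z.rename_axis("analyte_id").to_csv(
        outdir / "heatmap_severity.tsv", sep="\t"
    )

    for tp in ("24h", "72h"):
        v = volcano_table(log2m, outcome_grouping, tp)
        v.to_csv(outdir / f"volcano_NR_vs_R_{tp}.csv")
        sig = v[v["significant"]].sort_values("log2fc", ascending=False)
        print(f"{tp}: {len(sig)} mediators with >=1.5-fold NR/R difference "
              f"at adjusted p<0.05; top: {', '.join(sig.index[:5])}")

    patients = meta.drop_duplicates("patient_id").set_index("patient_id")
    trauma = patients[patients["group"] != "CONTROL"]
    summary = cohort_summary(trauma, trauma["group"])
    summary.to_csv(outdir / "cohort_summary.csv")
    print("cohort summary (NR vs R p-values):")
    print(summary[["p_value", "test_used"]].to_string())


if __name__ == "__main__":
    main()
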