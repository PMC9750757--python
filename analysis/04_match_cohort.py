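"""Case-control matching of non-resolvers to resolvers on age, sex and ISS,
followed by a matched re-analysis heatmap.

Writes matched pairs, the balance report and the matched heatmap under
results/matching/.
"""

import argparse
import json
from pathlib import Path

from traumapanel import (
    MatchSpec,
    classify_outcome,
    match_case_control,
    patients_from_frame,
    preprocess_panel,
    read_expression,
    zscore_matrix,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--out", default="results/matching")
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = Path(args.cohort)

    matrix, manifest, meta = read_expression(
        cohort / "expression.tsv", cohort / "sample_metadata.csv",
        cohort / "manifest.csv",
    )
    pdf = meta.drop_duplicates("patient_id").set_index("patient_id")
    patients = patients_from_frame(pdf.drop(columns=["timepoint", "group"]))
    by_group = {}
    for p in patients:
        by_group.setdefault(classify_outcome(p), []).append(p)

    spec = MatchSpec(age_tolerance=10, iss_tolerance=8, allow_many_to_one=True)
    res = match_case_control(by_group["NR"], by_group["R"], spec, seed=args.seed)
    print(f"matched {len(res.matched_cases)} NR cases to "
          f"{len(res.matched_controls)} R controls")
    print(f"post-match balance: age diff {res.balance['age_mean_diff']:.2f} y "
          f"(p={res.balance['age_p']:.3f}), ISS diff "
          f"{res.balance['iss_mean_diff']:.2f} (p={res.balance['iss_p']:.3f}), "
          f"sex p={res.balance['sex_p']:.3f}")
    (outdir / "balance_report.json").write_text(json.dumps(res.balance, indent=1))
    with open(outdir / "matched_pairs.csv", "w") as fh:
        fh.write("case_id,control_id\n")
        for a, b in res.pairs:
            fh.write(f"{a},{b}\n")

    matched_ids = {p.patient_id for p in res.matched_cases} | {
        p.patient_id for p in res.matched_controls
    }
    samples = meta.index[meta["patient_id"].isin(matched_ids)]
    log2m, _ = preprocess_panel(matrix, manifest, roles=("mediator",),
                                sample_ids=list(samples))

    def grouping(sid):
        return meta.loc[sid, "group"], meta.loc[sid, "timepoint"]

    heat = zscore_matrix(log2m, grouping)
    heat.z.rename_axis("analyte_id").to_csv(outdir / "heatmap_matched.tsv",
                                            sep="\t")
    print(f"matched heatmap: {heat.z.shape[0]} mediators x "
          f"{heat.z.shape[1]} cells")


if __name__ == "__main__":
    main()
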