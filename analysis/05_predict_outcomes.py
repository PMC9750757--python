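"""Outcome prediction from 72 h mediator levels.

Runs the bootstrap LASSO->linear-SVM ensemble on the R-vs-NR pool (out-of-bag
AUROC, median and 95% CI), a label-permuted control ensemble sharing the
same bootstrap draws, the paired significance test, quadratic-mean feature
importance (max scaled to 100), a covariate-augmented secondary model
(ISS/age/sex), and the PLS-DA projection.  Writes summaries under
results/prediction/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from traumapanel import (
    augment_covariates,
    bootstrap_ensemble,
    model_significance,
    plsda_scores,
    preprocess_panel,
    read_expression,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--out", default="results/prediction")
    parser.add_argument("--iterations", type=int, default=200)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--timepoint", default="72h")
    args = parser.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = Path(args.cohort)

    matrix, manifest, meta = read_expression(
        cohort / "expression.tsv", cohort / "sample_metadata.csv",
        cohort / "manifest.csv",
    )
    samples = meta.index[meta["group"].isin(["R", "NR"])
                         & (meta["timepoint"] == args.timepoint)]
    log2m, _ = preprocess_panel(matrix, manifest, roles=("mediator",),
                                sample_ids=list(samples))
    X = log2m.values.T
    y = (meta.loc[X.index, "group"] == "NR").astype(int).to_numpy()
    print(f"pool: {len(y)} patients ({y.sum()} NR), {X.shape[1]} mediators "
          f"at {args.timepoint}")

    def run(Xdf, tag):
        real = bootstrap_ensemble(Xdf.to_numpy(), y, B=args.iterations,
                                  draw_size=min(112, len(y)), seed=args.seed,
                                  feature_names=list(Xdf.columns))
        control = bootstrap_ensemble(Xdf.to_numpy(), y, B=args.iterations,
                                     draw_size=min(112, len(y)),
                                     seed=args.seed,
                                     feature_names=list(Xdf.columns),
                                     permute_labels=True)
        p = model_significance(real, control)
        real.comparison_p = p
        print(f"[{tag}] median OOB AUROC {real.median:.3f} "
              f"[{real.ci_low:.3f}, {real.ci_high:.3f}] vs permuted control "
              f"{control.median:.3f}; p = {p:.2e}")
        top = real.importance.head(5)
        print(f"[{tag}] top predictors: "
              + ", ".join(f"{k}={v:.0f}" for k, v in top.items()))
        payload = {"real": real.to_dict(), "control": control.to_dict()}
        (outdir / f"model_{tag}.json").write_text(json.dumps(payload, indent=1))
        return real

    run(X, "mediators")
    cov = meta.loc[X.index, ["iss", "age", "sex"]]
    run(augment_covariates(X, cov), "mediators_plus_covariates")

    scores, explained = plsda_scores(X.to_numpy(), y)
    pd.DataFrame(scores, index=X.index,
                 columns=["LV1", "LV2"]).assign(outcome=y).to_csv(
        outdir / "plsda_scores.csv")
    print(f"PLS-DA explained X-variance: LV1 {explained[0]:.1%}, "
          f"LV2 {explained[1]:.1%}")


if __name__ == "__main__":
    main()
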