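"""Evaluate the four random-forest screening models with repeated LOO.

Reads results/cohort.csv (from 01) and writes results/classifier_report.csv
with mean accuracy / sensitivity / specificity per model. Five evaluation
repeats with 100-tree forests keep the run short; pass --repeats/--trees to
reproduce heavier settings (e.g. 100 repeats of a 500-tree forest).
"""

import argparse
from pathlib import Path

import pandas as pd

import ddkscreen as dd

RESULTS = Path("results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--repeats", type=int, default=5)
    parser.add_argument("--trees", type=int, default=100)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table = pd.read_csv(RESULTS / "cohort.csv")
    specs = [
        dd.ModelSpec(
            model_id=m, n_repeats=args.repeats, n_estimators=args.trees, seed=args.seed + m
        )
        for m in sorted(dd.MODEL_FEATURES)
    ]
    _, summary = dd.run_model_suite(table, specs)
    summary.to_csv(RESULTS / "classifier_report.csv", index=False)
    print("Leave-one-out performance (means over repeats, %):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
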