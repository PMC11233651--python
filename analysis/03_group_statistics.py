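"""Compare the emulated PD and control groups on the 11 planned tests.

Reads results/cohort.csv (from 01), runs the Mann-Whitney comparisons with
joint FDR correction and rank-biserial effect sizes, and writes
results/comparisons.csv. The five parameter/condition pairs expected to
separate the groups are the whispering percentages under Masked and
Replaced feedback, errors/s and reaction time under Reduced feedback, and
rhythm consistency under Normal feedback.
"""

from pathlib import Path

import pandas as pd

import ddkscreen as dd

RESULTS = Path("results")


def main() -> None:
    table = pd.read_csv(RESULTS / "cohort.csv")
    res = dd.compare_groups(table)
    res.to_csv(RESULTS / "comparisons.csv", index=False, float_format="%.6g")
    show = res[
        ["parameter", "condition", "u_stat", "p_raw", "p_fdr", "r_rank_biserial", "significant"]
    ].copy()
    print(f"{int(res.significant.sum())} of {len(res)} tests FDR-significant at alpha=0.05:")
    print(show.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
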