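"""Effect sizes and required sample sizes per method and contrast.

Two power tables: one from the reference (published-summary) group
statistics — the reproduction of the headline sample-size numbers — and
one from the simulated cohorts' own sample statistics, showing that the
full simulate→measure→estimate loop recovers the same ordering of methods.
"""

import argparse
from pathlib import Path

import pandas as pd

from longivol import power_analysis, subject_pvc
from longivol.simulate import REFERENCE_GROUP_STATS
from longivol.stats import CohortTable, apply_exclusion

RESULTS = Path(__file__).resolve().parents[1] / "results"
CONTRASTS = (("CTRL", "MCI"), ("CTRL", "AD"))


def table_from_stats(stats_by_method) -> pd.DataFrame:
    rows = []
    for method, stats in stats_by_method.items():
        for g1, g2 in CONTRASTS:
            if g1 not in stats or g2 not in stats:
                continue
            res = power_analysis(*stats[g1], *stats[g2])
            rows.append({"method": method, "contrast": f"{g1}-{g2}",
                         "cohen_d": round(res.cohen_d, 3),
                         "n_per_group": res.n_per_group})
    return pd.DataFrame(rows)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--input", default=RESULTS / "pvc_simulated.csv")
    args = parser.parse_args()

    ref = table_from_stats(REFERENCE_GROUP_STATS)
    print("from reference summary statistics:")
    print(ref.to_string(index=False))

    sim_stats = {}
    if Path(args.input).exists():
        subj = subject_pvc(apply_exclusion(CohortTable.from_csv(args.input)))
        for method, sdf in subj.groupby("method"):
            gs = sdf.groupby("group")["pvc"].agg(["mean", "std"])
            sim_stats[method] = {g: (gs.loc[g, "mean"], gs.loc[g, "std"])
                                 for g in gs.index}
        sim = table_from_stats(sim_stats)
        print("\nfrom one simulated cohort per method:")
        print(sim.to_string(index=False))
        sim["source"] = "simulated"
    else:
        sim = pd.DataFrame()

    ref["source"] = "reference"
    RESULTS.mkdir(exist_ok=True)
    pd.concat([ref, sim], ignore_index=True).to_csv(
        RESULTS / "power_table.csv", index=False)
    print(f"\nwrote power_table.csv to {RESULTS}")


if __name__ == "__main__":
    main()
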