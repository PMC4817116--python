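#!/usr/bin/env python
"""Discriminative power of the seven descriptors.

First compares each inhibitor collection with every reference library per
descriptor (decision tree at alpha = 0.05, star-annotated).  Then, for each
PPI-target family with at least 5 compounds, counts how many reference
libraries differ significantly per descriptor, and tabulates the histogram
of those counts.  Writes star table, count table and histogram to results/.
"""

from pathlib import Path

import pandas as pd

from ippispace import compare_two, count_significant
from ippispace.stats import significance_histogram
from ippispace.synth import DISCRIMINATIVE_DESCRIPTORS, read_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05


def main() -> None:
    table = read_table(RESULTS / "descriptors.csv")
    refs = sorted(l for l in table["dataset"].unique() if l.startswith("ref_"))
    descriptors = list(DISCRIMINATIVE_DESCRIPTORS)

    # star-annotated inhibitor-vs-reference comparisons
    rows = []
    for ippi in ("iPPI-DB", "TIMBAL"):
        a = table[table["dataset"] == ippi]
        for ref in refs:
            b = table[table["dataset"] == ref]
            for d in descriptors:
                res = compare_two(a[d].to_numpy(), b[d].to_numpy(), ALPHA)
                rows.append({
                    "ippi_dataset": ippi, "reference": ref, "descriptor": d,
                    "test": res.test_used, "p_value": res.p_value,
                    "direction": res.direction, "stars": res.star_level,
                })
    star_table = pd.DataFrame(rows)
    star_table.to_csv(RESULTS / "descriptor_star_table.csv", index=False)
    n_sig = (star_table["stars"] != "ns").sum()
    print(f"{n_sig}/{len(star_table)} inhibitor-vs-reference comparisons significant")

    # per-target significance counts (families with >= 5 compounds only)
    targets = sorted(table.loc[table["target"].notna(), "target"].unique())
    counts = count_significant(table, targets, refs, descriptors, ALPHA)
    counts.to_csv(RESULTS / "target_significance_counts.csv")
    print(f"{counts.shape[0]} of {len(targets)} PPI-target families analysed "
          f"(families under 5 compounds dropped)")

    hist = significance_histogram(counts, n_reference=len(refs))
    hist.to_csv(RESULTS / "significance_histogram.csv")
    best = counts.sum(axis=0).idxmax()
    print(f"most discriminative descriptor across targets: {best}")


if __name__ == "__main__":
    main()
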