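#!/usr/bin/env python
"""Build the synthetic study collection.

Generates (a) the two PPI-inhibitor collections at their published sizes
and descriptor statistics, split into illustrative PPI-target families, and
(b) four illustrative reference ("non-iPPI") libraries with shifted
descriptor profiles.  Writes the joined descriptor table and the generating
specs under results/.
"""

from pathlib import Path

from ippispace import DatasetSpec, default_specs, generate_collection
from ippispace.synth import write_specs, write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20160401

# Illustrative PPI-target families: modest target-specific shifts of the
# inhibitor profile.  One family is deliberately below the 5-compound rule.
TARGET_FAMILIES = [
    # (name, n, MW shift, EDmin3 shift, IW4 shift)
    ("Bcl2", 90, 60.0, -0.10, 0.3),
    ("MDM2", 70, -20.0, -0.05, -0.2),
    ("Xiap", 60, 30.0, -0.12, 0.5),
    ("IL2", 40, 10.0, 0.05, 0.4),
    ("Brd", 25, -40.0, 0.08, -0.3),
    ("CD80", 8, 80.0, 0.00, 0.0),
    ("E1", 4, 0.0, 0.00, 0.0),  # dropped downstream (below 5 compounds)
]

REFERENCE_LIBRARIES = [
    # (name, n, MW, AlogP, aromatic_ratio, CW2, IW4, glob, EDmin3) -- means
    ("ref_drug_like", 900, 380.0, 3.0, 0.25, 2.15, 2.3, 0.11, -2.45),
    ("ref_commercial", 800, 350.0, 3.2, 0.30, 2.10, 2.2, 0.10, -2.40),
    ("ref_natural", 300, 420.0, 2.5, 0.18, 2.05, 2.4, 0.15, -2.55),
    ("ref_kinase", 500, 410.0, 3.6, 0.36, 2.08, 2.5, 0.10, -2.50),
]

DESC = ("MW", "AlogP", "aromatic_ratio", "CW2", "IW4", "glob", "EDmin3")


def family_specs():
    base = default_specs()["iPPI-DB"]
    specs = []
    for i, (name, n, d_mw, d_ed, d_iw) in enumerate(TARGET_FAMILIES):
        means = dict(base.means)
        means["MW"] += d_mw
        means["EDmin3"] += d_ed
        means["IW4"] += d_iw
        specs.append(
            DatasetSpec(
                name="iPPI", n=n, means=means, sds=base.sds, bounds=base.bounds,
                target=name, seed=SEED + i,
            )
        )
    return specs


def reference_specs():
    base = default_specs()["iPPI-DB"]
    sds = {
        "MW": 120.0, "AlogP": 1.7, "aromatic_ratio": 0.10, "CW2": 0.20,
        "IW4": 1.0, "glob": 0.08, "EDmin3": 0.25,
    }
    specs = []
    for i, (name, n, *means) in enumerate(REFERENCE_LIBRARIES):
        specs.append(
            DatasetSpec(
                name=name, n=n, means=dict(zip(DESC, means)), sds=sds,
                bounds=base.bounds, seed=SEED + 100 + i,
            )
        )
    return specs


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    whole = [  # the two inhibitor collections as wholes, published sizes
        s for s in default_specs().values()
    ]
    specs = whole + family_specs() + reference_specs()
    table = generate_collection(specs)
    write_table(table, RESULTS / "descriptors.csv")
    write_specs(specs, RESULTS / "dataset_specs.yaml")
    print(f"{len(table)} compounds across {table['dataset'].nunique()} datasets")
    print(f"PPI-target families: {table['target'].dropna().nunique()}")
    print(f"wrote {RESULTS / 'descriptors.csv'}")


if __name__ == "__main__":
    main()
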