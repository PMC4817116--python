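# ippispace

Quantifying the imbalance in chemical space between inhibitors of
protein–protein interactions (iPPIs) and conventional compound libraries.

Low-molecular-weight PPI inhibitors occupy an unusual corner of chemical
space — they are larger (MW ≈ 540 ± 145 g·mol⁻¹), more hydrophobic
(AlogP ≈ 4.6), more aromatic, and carry distinctive 3D shape signatures
(globularity, and the molecular-field descriptors EDmin3, CW2, IW4).
`ippispace` is an analysis toolkit for measuring how strongly any two
compound collections overlap in a descriptor-based chemical space, for
counting which descriptors discriminate PPI-inhibitor families from
reference libraries, and for clustering both ligand space and binding-pocket
space into coherent target classes.

## The overlap score Δ

Given a collection of datasets described by numeric molecular descriptors:

1. all compounds are pooled, each descriptor standardized, and a full-rank
   PCA fitted (components `i = 1..n`, variance fractions `V_i`,
   `Σ V_i = 100 %`);
2. on each component, a Gaussian KDE (rule-of-thumb bandwidth
   `0.9·min(SD, IQR/1.34)·n^(−1/5)`, 512 grid points) estimates each
   dataset's density `f`;
3. the one-component overlap of datasets A and B is Weitzman's measure
   `δ_i = ∫ min(f_A, f_B) dx`;
4. the overlap score is the variance-weighted mean
   `Δ = Σ_i δ_i·V_i / Σ_i V_i  ∈ [0, 1]`,
   1 for identical datasets, 0 for disjoint ones.

`1 − Δ` then serves as a distance for Ward agglomerative clustering of the
datasets; binding pockets are clustered the same way from Euclidean
distances between 117-entry pocket descriptor vectors (89 cavity-point
descriptors + 10 per-distance sums + 18 shape descriptors), and each
cluster is characterized by the descriptors that separate it from all other
clusters at α = 1e-4.

Because the real source collections (iPPI-DB, TIMBAL, MDDR, BindingDB
subsets, commercial libraries, …) cannot be redistributed, the package
ships a synthetic generator that reproduces their published per-descriptor
mean ± SD at the published dataset sizes (truncated Gaussians,
moment-calibrated under bounds).

## Worked example

```python
import ippispace as ip

table = ip.generate_collection(ip.default_specs())   # 3,248 synthetic iPPIs
m = ip.pairwise_overlap(table, list(ip.DISCRIMINATIVE_DESCRIPTORS))
print(round(m.values.loc["iPPI-DB", "TIMBAL"], 3))
```

prints

```
0.899
```

— the two PPI-inhibitor collections, generated only from their published
descriptor statistics, overlap almost completely in chemical space
(Δ ≈ 0.9; the published estimate on the real data is 0.88), in contrast to
e.g. a 10-SD-separated pair, which scores near 0.

The full analysis is organised as numbered drivers:

```bash
python analysis/01_simulate_datasets.py      # synthetic collections + target families
python analysis/02_descriptor_significance.py# star tables + significance counts
python analysis/03_chemspace_overlap.py      # pairwise Δ matrix
python analysis/04_pocket_vectors.py         # 117-descriptor pocket vectors
python analysis/05_cluster_spaces.py         # Ward clustering of both spaces
```

Each driver prints what it found and writes its tables under `results/`.
A `ippispace` command-line tool exposes the same stages
(`simulate`, `curate`, `compare`, `overlap`, `pockets`, `cluster`, `run`).

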