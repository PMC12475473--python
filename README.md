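# striaging

Quantitative analysis of regionally enriched cell subtypes and their
asymmetric change with age in spatial single-cell maps of the striatum.

Imaging-based spatial transcriptomics (MERFISH-style) and droplet scRNA-seq
both resolve transcriptomic subtypes of striatal glia — astrocytes in
particular — but asking *where* a subtype lives along the dorsal-ventral
axis, and *how* its territory and abundance shift between young and aged
animals, needs statistics that do not confound subtype abundance with
local cell density. This package implements that analysis end to end:

- **QC and normalization** — platform-specific filters (droplet: ≥ 300
  detected genes, ≤ 20% mitochondrial counts, genes in > 3 cells;
  MERFISH: ≥ 10 detected genes and volume ≥ 50 µm³) and total-count
  log normalization, `ln(1 + 10^4 · x_cg / T_c)`.
- **Two-tier clustering and age dominance** — PCA (30 PCs) → shared
  nearest-neighbor graph → Leiden modularity communities (resolution 0.08,
  then 0.10 within one cell class); a subcluster is *aged-* or
  *young-dominant* when strictly more than 70% of its cells come from one
  age group, otherwise *common*.
- **Hurdle differential expression** — per gene, a logistic model of
  detection and a Gaussian model of expression among detected cells, both
  with the cellular detection rate (CDR) as covariate, combined by a
  likelihood-ratio χ² (df = 2); Benjamini–Hochberg FDR; aging DEGs at
  |log2FC| > 0.25, FDR < 0.05; cluster markers by the in/out detection
  ratio `pct_in / pct_out ≥ 2` at FDR < 0.05.
- **Regional expression probability** — with `n[a,y]` subtype-*a* cells in
  500 µm dorsal-ventral bin *y* and `N[y]` cells in the bin, the bin share
  `r[a,y] = n[a,y] / N[y]` is renormalized per subtype to sum to 1 across
  bins, giving a spatial probability profile `P[a,·]` free of both subtype
  abundance and per-bin density; aging change is `Δ[a,y] = P_aged − P_young`,
  tested by a two-way (age × subregion) F with a label-permutation p-value.
- **Aging module score** — per cell, mean expression of a gene program
  (top-20 aging DEGs) minus the mean of 100 expression-matched control
  genes per program gene, drawn from average-expression strata.
- **Detection power** — repeated subsampling and reclustering; a subtype is
  detected in a replicate when some cluster reaches Jaccard ≥ 0.5 with its
  subsampled members.
- **Gene-list set operations** — Venn region counts and UpSet-style
  exclusive intersections (exact membership patterns) across 2–6 lists,
  with case-insensitive symbol matching for mouse/human comparisons.

Everything runs on a built-in synthetic data generator with known ground
truth (negative-binomial counts, per-cell capture noise, planted markers,
dorsal-ventral gradients and an aging program), so the whole pipeline is
testable without any download.

## Worked example

```python
import striaging as st

# simulate a two-age striatal map in which subtype A4 shifts two bins
# dorsally in aged animals
cfg = st.SimulationConfig.dorsal_shift(seed=1)
cells, counts, truth = st.simulate_dataset(cfg)
norm = st.normalize_log(counts)

calls = st.classify_dominance(truth.subtype_labels,
                              cells.set_index("cell_id")["age"])
print(calls.to_string(index=False))
```

```
cluster_id  n_young  n_aged  frac_aged  label
        A1      400     590   0.595960 common
        A2      394     319   0.447405 common
        ...
        A7      164     136   0.453333 common
```

A1 expands in aged animals (59.6% aged) but stays below the strict 70%
bar, so every subtype is called *common* — composition change alone is not
dominance. The planted spatial shift, however, is unmistakable:

```python
meta = cells.set_index("cell_id")
bins = st.assign_subregions(meta, st.SubregionBinning(origin_y=0.0))
young = (meta["age"] == "young").to_numpy()
prof_y = st.expression_probability(
    st.count_subregions(truth.subtype_labels[young], bins[young], 6))
prof_a = st.expression_probability(
    st.count_subregions(truth.subtype_labels[~young], bins[~young], 6))
print(st.age_shift(prof_y, prof_a).loc["A4"].round(3).to_string())
```

```
bin0    0.402
bin1    0.219
bin2   -0.061
bin3   -0.326
bin4   -0.175
bin5   -0.058
```

Subtype A4's probability mass moves out of its young territory (bins 3–4)
into the dorsal bins 0–1; per subtype the shifts sum to zero by
construction. The planted 20-gene aging program is likewise recovered by
the expression-matched module score (aged − young mean gap ≈ 1.02 in this
simulation).

The same stages are available as a CLI:

```sh
striaging simulate --out data/ --seed 1
striaging run --in data/ --out results/ --seed 1
striaging overlap --lists lists.csv --out upset.tsv
```

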