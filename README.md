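# growthmodulon

Identification of a bacterial **growth modulon** — the set of genes whose
transcription tracks the specific growth rate itself, independently of which
nutrient limitation the culture is recovering from — from bulk RNA-Seq series
sampled along growth-rate transitions.

The intended user is a microbial-systems researcher with (i) growth curves
(cell dry weight over time, with the percent viability of the inoculum),
(ii) a gene × sample raw-count matrix whose samples are annotated with the
differential growth rate μ at sampling, and (iii) a curated regulatory
network (regulator → target edges).  The package also ships a synthetic-data
generator that emulates the full study design (three pre-culture limitations
× target rates μ ∈ {0, 0.1, 0.2, 0.3, 0.4} h⁻¹ × three biological
replicates, with realistic drop-outs) and plants a known modulon, so the
entire pipeline can be exercised and validated at desk scale.

## The method

1. **Viability-adjusted kinetics.** After a long stationary pre-culture a
   fraction of the inoculum is dead; CDW measurements cannot tell. The
   differential growth rate between consecutive biomass samples is computed
   on viable biomass,
   `μ_diff = ln[(c_t − d)/(c_{t−1} − d)] / Δt` with dead-biomass offset
   `d = c₀(1 − υ₀/100)`, interpolated piecewise-linearly between interval
   midpoints, and used to pick the transcriptome samples closest to the
   target rates.
2. **Normalization and sample structure.** Relative log expression (RLE,
   median-of-ratios) size factors; between-sample dissimilarity as the
   deviance of a Poisson log-linear model with size-factor offsets;
   complete-linkage hierarchical clustering of samples.
3. **Rate-course differential expression.** Per condition, a cubic-in-μ
   negative-binomial GLM per gene,
   `log E[count] = log s + β₀ + β₁μ + β₂μ² + β₃μ³`, with the NB dispersion
   pooled across genes and a quasi-likelihood F-test against the
   intercept-only model; BH FDR at α = 0.05 and per-condition |log₂FC|
   cutoffs (0.73 / 0.73 / 0.6 — the carbon cutoff is lower because that
   condition lacks the μ = 0 sample).
4. **Modulon identification.** Intersect the three DEG sets, then keep only
   genes whose fitted log₂FC-vs-μ profiles (anchored to 0 at the reference
   rate μ = 0.4 h⁻¹) correlate across all condition pairs at Pearson
   r ≥ 0.7 — genes responding to the growth rate the same way regardless of
   pre-culture history.
5. **Profile clustering.** Partition the modulon into k = 4 expression-shape
   clusters (Ward linkage on 1 − Pearson of condition-averaged profiles),
   with fixed label semantics: 1 steady rise, 2 late sharp rise, 3 rise then
   fall on the last rate interval, 4 steady fall.
6. **Regulon enrichment.** Upper-tail hypergeometric over-representation of
   each regulator's target set within the modulon (universe = genes retained
   in the count matrix), BH-controlled; per-regulon overlap broken down by
   profile cluster; export of the significant regulator → gene subnetwork.

## Worked example

```python
import growthmodulon as gm
from growthmodulon.counts import drop_all_zero_genes
from growthmodulon.de import DEFAULT_LFC_CUTOFFS, call_degs, fit_rate_course

cfg = gm.SimulationConfig(seed=1)            # the emulated 40-sample design
counts, meta, truth = gm.simulate_counts(cfg)
counts = drop_all_zero_genes(counts)
sf = gm.rle_size_factors(counts)

fits, degs = {}, []
for cond in meta["condition"].unique():
    sel = meta["condition"] == cond
    ids = meta.loc[sel, "sample_id"].tolist()
    f = fit_rate_course(counts[ids], meta.loc[sel, "mu"].to_numpy(float),
                        sf[ids], condition=cond)
    fits[cond] = f
    d = call_degs(f, 0.05, DEFAULT_LFC_CUTOFFS[cond])
    degs.append(d)
    print(f"{cond}: {len(d.genes)} DEGs")

result = gm.identify_modulon(degs, fits, similarity_threshold=0.7)
result = gm.cluster_profiles(result, fits, k=4)
print(f"shared DEGs: {len(result.intersection_genes)}")
print(f"growth modulon: {len(result.modulon_genes)} genes")
print(result.mean_cluster_profiles.round(2))
```

prints

```
phosphate: 470 DEGs
nitrogen: 473 DEGs
carbon: 479 DEGs
shared DEGs: 400
growth modulon: 399 genes
          0.1   0.2   0.3  0.4
cluster
1       -1.11 -0.73 -0.36  0.0
2       -1.47 -1.33 -0.77 -0.0
3       -0.07  0.88  1.39  0.0
4        1.15  0.75  0.35 -0.0
```

The generator planted 400 modulon genes plus 150 genes responding in only
one or two conditions; the pipeline recovers 399 of the 400 (one false
negative, no false positives).  The cluster table shows the mean log₂ fold
change of each shape cluster relative to the μ = 0.4 h⁻¹ reference: cluster
1 rises steadily with μ, cluster 2 stays low until μ ≈ 0.2 and then climbs
sharply, cluster 3 peaks at μ = 0.3 and drops on the last interval, cluster
4 falls monotonically.  Enriching the simulated regulatory network flags
exactly the five planted regulators at BH-adjusted p < 0.05.

The same run is available from the shell:

```sh
modulon run --config config.yaml      # simulate → kinetics → cluster → DE →
                                      # modulon → enrichment, with a manifest
modulon simulate --outdir sim --seed 1
modulon de --counts sim/counts.tsv --meta sim/sample_meta.tsv \
           --condition phosphate --outdir out
```

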