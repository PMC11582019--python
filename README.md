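# resptyper

Time-resolved response typing of soil bacterial and archaeal communities
under factorial **top-down** (bacterivorous nematode grazing) × **bottom-up**
(maize litter input) control.

## The problem

Soil microcosm experiments that cross a grazer addition (±A, a bacterivorous
nematode such as *Acrobeloides buetschlii*) with a resource addition (±M,
maize litter) and sample destructively over an incubation time course (days
0, 4, 8, 16, 32; day-0 samples shared between the ±A arms of each maize
level — 54 molecular samples in the emulated design) produce 16S rRNA gene
ASV count tables, qPCR total-copy measurements, and alkali-trap CO₂
titrations. `resptyper` turns these into population-level answers: *which*
dominant taxa respond, *how* their abundance trajectories are shaped by
grazing versus resources, and *when* top-down control overtakes bottom-up
control.

## The method

1. **Absolute abundance** — read proportions per sample are scaled by the
   qPCR-measured total, `x̂ᵢₛ = (cᵢₛ / Σᵢ cᵢₛ) · Tₛ` (copies · g dry soil⁻¹).
2. **Selection cascade** — an ASV is kept if it is *dominant* in ≥ 1 sample
   (among the top ⌊²D + ½⌋ taxa, with ²D the inverse Simpson Hill number of
   that sample), *prevalent* (detected in ≥ 2/3 replicates in every
   treatment × day cell), and *responsive*: ranked by the summed
   (max − min) of its replicate-mean trajectory over the four treatments,
   the shortest prefix covering 80 % of the total range is retained
   (Pareto selection).
3. **Response typing** — each (ASV, treatment) trajectory is screened for
   temporal stability (range < θ · median, default θ = 0.75), z-scored,
   and all non-stable trajectories are pooled into one k-means clustering
   (k = 9, best of 25 starts; k pre-screened by elbow, silhouette and gap
   statistics). The nine centroids are merged by complete-linkage
   agglomeration on (1 − Pearson r) into five groups, each labelled with
   the best-correlated archetype: **A** steady decline, **B** minimum at
   day 8 with recovery, **C** steady increase, **D** peak at day 4,
   **E** peak at day 8.
4. **Patterns & succession** — the 4-tuple of types per ASV over
   (−A/−M, −A/+M, +A/−M, +A/+M) is ranked by summed median abundance;
   grazing-susceptible ASVs (decline under +A/−M only) split into
   succession groups by their +A/+M type: I (A), II (D), III (E).
5. **Beta diversity** — Bayesian-multiplicative zero replacement, CLR
   transform, Aitchison-distance PCA, and redundancy-analysis variance
   partitioning (adjusted R²) over maize, nematode and day factors.
6. **Respiration** — CO₂ release from titration volumes,
   `rate = (HCl_blank − HCl_sample) · 2.2 · 1000 / (soil_dw · hours)`
   (μg CO₂ g⁻¹ h⁻¹), with a Gaussian-kernel smooth to locate the day of
   maximum respiration.

A synthetic-data module generates complete datasets (counts, qPCR,
metadata, taxonomy, titrations) with planted response archetypes and known
ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import resptyper as rt

ds, truth = rt.simulate_dataset(rt.SimConfig(s_asvs=200, depth=10_000), seed=7)
abund = rt.to_absolute(ds.counts, ds.qpcr)
report = rt.select_responsive_asvs(abund, ds.counts, ds.meta, ds.design)
print(f"dominant: {len(report.dominant_set)}  prevalent: {len(report.prevalent_set)}  "
      f"responsive: {len(report.responsive_set)}  coverage: {report.coverage:.3f}")

assignments, clf = rt.assign_response_types(
    abund, ds.meta, ds.design, sorted(report.responsive_set), seed=42)
print(assignments["response_type"].value_counts().to_dict())

from resptyper.patterns import assemble_patterns, rank_patterns, succession_groups
pats = assemble_patterns(assignments, abund)
top, cov = rank_patterns(pats, coverage=0.8)
print(f"{len(pats.groupby(list(rt.CANONICAL_TREATMENTS)))} distinct patterns; "
      f"top {len(top)} cover {cov:.1%} of summed median abundance")
```

prints

```
dominant: 146  prevalent: 191  responsive: 69  coverage: 0.800
{'D': 81, 'C': 73, 'E': 60, 'A': 28, 'B': 20, 'STABLE': 14}
51 distinct patterns; top 27 cover 80.4% of summed median abundance
```

Of 200 simulated ASVs, 146 are dominant somewhere, 191 consistently
detected, and 69 carry 80 % of all abundance change; their 276
(ASV, treatment) trajectories distribute over the five archetypes plus a
stable remainder, and 27 of the 51 cross-treatment patterns account for
80.4 % of the community's median abundance.

The same stages are available as a CLI:

```bash
resptyper all --out results/              # synthetic preset, all stages
resptyper classify --counts c.tsv --meta m.tsv --qpcr q.tsv --out results/
resptyper respire --titrations t.tsv --out results/
```

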