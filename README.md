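# spatialtil

Spatial tumor-immune biomarkers from multiplex-immunofluorescence tissue
microarray (TMA) cell tables, with the survival and association inference
to evaluate them.

## The problem

Tumor-infiltrating lymphocyte (TIL) *counts* are prognostic in highly
infiltrated breast cancers, but most breast cancers (ER+ in particular)
have low-to-moderate infiltration, where the *placement* of CD8+ T-cells
relative to tumor cells may matter more than their number. Cytotoxic
T-cells must contact tumor cells to kill them, so distance-based summaries
are a natural way to quantify an effective immune response.

`spatialtil` takes per-cell tables exported from a segmentation tool (one
row per cell: core and participant IDs, centroid x/y in microns, mean
intensity per channel for Hoechst / CK / CD8 / FoxP3) and computes, per
participant:

- **proximity** `= 3 − mean(log10 NND)` — where NND is the nearest-neighbor
  distance (µm) from each tumor cell to its closest CD8+ T-cell within the
  same core, truncated at 1000 µm. High proximity: CD8 cells sit close to
  tumor cells. Range [0, 3] for NNDs in [1, 1000] µm.
- **consistency** `= 1 − var(log10 NND)` — high consistency: uniform
  tumor–CD8 spacing across the tumor.
- **lymphocyte count** — CD8 + Treg cells over quality-passed cores.

Cells are classified by per-channel intensity thresholds (Treg when CD8
and FoxP3 both exceed, CD8 when only CD8 exceeds, tumor only when CK
exceeds and no lymphocyte marker does — lymphocyte markers take priority),
cores with too few cells are removed, log10 NNDs are pooled across a
participant's cores, and the metrics are binarized at cohort cutpoints
(first quartile for proximity, median for consistency and count). The
inference layer provides Kaplan-Meier curves with 95% log-log bounds,
log-rank tests, Cox proportional-hazards fits (Efron or Breslow ties) with
Wald hazard-ratio intervals, nested likelihood-ratio tests, the
Grambsch-Therneau proportionality check, Kruskal-Wallis and Spearman
tests, and 2×2 odds ratios (sample estimate with Woolf CI, or exact
conditional MLE).

Because the underlying patient cohort is available only on request, the
package ships a seeded synthetic TMA cohort generator (clustered tumor
point process, three lymphocyte infiltration modes, class-separable
log-normal marker intensities, proportional-hazards recurrence times,
logistic label models) so every stage is testable end to end with known
truth — plus the published biomarker-by-immune-class contingency counts as
a packaged fixture.

## Worked example

Reproduce the published biomarker-vs-molecular-class association analysis
from the packaged contingency counts:

```sh
$ spatialtil assoc --table1
proximity vs adaptive_enriched (immune_class): OR = 4.9 [3.2, 7.4]
consistency vs adaptive_enriched (immune_class): OR = 2.4 [1.8, 3.2]
lymphocyte_count vs adaptive_enriched (immune_class): OR = 6.0 [4.4, 8.2]
proximity vs agi (genomic_instability): OR = 1.3 [1.0, 1.8]
consistency vs agi (genomic_instability): OR = 1.4 [1.0, 1.8]
lymphocyte_count vs agi (genomic_instability): OR = 2.6 [2.0, 3.4]
```

High proximity is strongly associated with the adaptive-enriched immune
class (odds ratio 4.9), while genomic instability is mainly associated
with lymphocyte count (2.6) — spatial placement and bulk count carry
different information. (Intervals are Woolf log-normal; the exact
conditional method is available via `odds_ratio_2x2(..., method="conditional_mle")`.)

Run the whole pipeline on a simulated cohort from Python:

```python
import spatialtil as st
from spatialtil.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulation=st.SimulationConfig(
        n_participants=120, cores_per_participant=2, tumor_intensity=300,
        lymphocyte_intensity=60, stroma_intensity=120, seed=7),
    qc_min_tumor=50, qc_min_total=100, seed=7)
bundle = run_pipeline(cfg, "out/run7")
```

which classifies every simulated cell, QC-filters cores, computes and
binarizes the metrics, and fits the survival models, printing (via the
returned bundle):

```
univariate_proximity: HR(low vs high) = 2.42 [0.98, 5.97]
univariate_consistency: HR(low vs high) = 0.67 [0.27, 1.64]
univariate_lymphocyte_count: HR(low vs high) = 1.79 [0.75, 4.27]
log-rank proximity p = 0.04766
```

The generator's default hazard places a log(2) effect on low proximity,
and the fitted low-vs-high hazard ratio of 2.42 (95% CI [0.98, 5.97])
recovers it within sampling noise at this small cohort size. Outputs
(metrics, KM curves, Cox summaries, tests, exclusions with reasons, and a
manifest with the config hash, seed, cutpoints, and participant counts at
each filter step) are written as CSV/JSON to the run directory; identical
config + seed gives byte-identical outputs. The same stages are exposed as
CLI subcommands (`spatialtil simulate / classify / metrics / survival /
assoc / run`) for file-based use.

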