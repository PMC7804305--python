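# tempomics

Temporal trend classification for longitudinal multi-omics time series:
from analyte × timepoint intensity matrices to autocorrelation-based trend
classes, two-tier trend clusters, cross-omics combined classes, and
class-wise weighted expression networks.

## What it does

1. **Preprocess** (`tempomics.preprocess`) — tag zeros as missing, floor
   sub-noise intensities, drop series with more than 1/4 of timepoints
   missing or constant values, subtract a reference timepoint, build paired
   per-timepoint difference series (TFΔ = TFH2 − TFH1) to cancel shared
   within-day variation, Box-Cox-transform intensity-type layers per sample,
   and unit-normalize every series.
2. **Classify** (`tempomics.spectral`) — Lomb–Scargle periodogram on the
   Fourier grid (valid with missing/uneven samples), inverse Fourier
   transform to lag autocorrelations ρ₀..ρ⌊N/2⌋, bootstrap null cutoffs per
   lag (resampling the pooled observed values, default p = 0.01 with 100,000
   resamples), then assign each series to the lowest significant lag class
   (*Lag l*), or to *SpikeMax* / *SpikeMin* on single-timepoint extremes, or
   leave it unclassified.
3. **Cluster** (`tempomics.cluster`) — within each class, groups (G#) by
   autocorrelation shape, then subgroups (S#) by intensity shape, which
   separates phase/sense. Agglomerative, average linkage, k by mean
   silhouette.
4. **Integrate** (`tempomics.integrate`) — join classes across omic layers
   within a time frame (ids namespaced `omic:analyte`) and re-cluster the
   combined classes.
5. **Network** (`tempomics.network`) — per class, edge weights
   w = 1/(d + 0.0001) from Euclidean distances (mean imputation for missing
   values), edges kept above the one-tailed quantile q(N) = 0.8 for N < 500,
   1 − 100/N otherwise; exported as JSON.
6. **Simulate** (`tempomics.simulate`) — a full synthetic study generator
   (paired hourly frames, daily frame, circadian/perturbation/spike
   archetypes, zero-inflation, missingness) with ground-truth labels, so the
   whole pipeline is testable offline.

## CLI

```sh
# full synthetic study end to end
tempomics run --simulate --seed 1 --out out/

# or stage by stage
tempomics simulate --design design.yaml --seed 1 --out data/
tempomics classify --config cfg.yaml --in data/mRNA_TFH1.tsv \
    --omic mRNA --frame TFH1 --out out/
tempomics cluster --in out/classified_mRNA_TFH1.tsv --out out/clustered.tsv
tempomics network --in out/classified_mRNA_TFD.tsv --frame TFD --out nets/
tempomics summarize --in out/classified_mRNA_TFH1.tsv --out counts.json
```

Matrices are delimited text (TSV/CSV): first row sampling times, first
column analyte ids, empty cells or `NA` for missing values. One YAML/JSON
config (see `tempomics.config.StudyConfig`) drives every stage. Exit codes:
0 success, 2 config error, 3 data error.

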