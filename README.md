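# fragilemap

Genome-wide chromosome-fragility analysis from two-channel genomic
microarrays.

When replication forks stall — for example under hydroxyurea (HU) in
checkpoint-deficient budding-yeast mutants such as *mec1* — single-stranded
DNA (ssDNA) accumulates at the forks and the underlying loci later break.
Both ssDNA and double-strand-break (DSB) ends can be labeled and
cohybridized against a control sample on a tiling microarray, giving a
per-probe two-channel fluorescence measurement along every chromosome.
`fragilemap` is the analysis side of that experiment: it turns the raw
per-probe measurements into smoothed ratio profiles, calls significant
break/ssDNA sites, correlates profiles between samples, and tests whether
the break sites are closer to categorized replication origins than chance
would allow. A synthetic-data generator produces array-like measurements
with planted enrichment structure so every stage is testable end to end.

## The model and statistics

**Ratio profile.** For each unflagged probe, the background-subtracted
signal in the experimental channel is divided by that of the control
channel after each channel is normalized to its genome-wide total:

    r_i = (E_i / Σ_j E_j) / (C_i / Σ_j C_j),   E_i = exp_signal_i − exp_bg_i

Profiles are smoothed per chromosome by Lowess — locally weighted linear
regression with tricube weights over a fixed **6 kb genomic window**
(± 3 kb around each probe midpoint); smoothing never crosses chromosome
boundaries.

**Site calling.** Significant break/ssDNA sites are probes whose smoothed
ratio strictly exceeds the genome-wide median of the profile. Peaks (for
validating known cut sites) are per-chromosome local maxima with a
prominence of at least half the interquartile range.

**Association test.** Distances between sites and features (checked or
unchecked replication origins, centromeres, restriction/HO cut sites) are
measured midpoint to midpoint; a site is "near" a feature when its nearest
same-chromosome feature lies within 6 kb (inclusive), matching the
smoothing window. Significance comes from a randomization test: an equal
number of positions is drawn uniformly without replacement from the
unflagged probes of the array, the near count is recomputed for each of
10,000 draws, and

    P = #{draws with count ≥ observed} / 10,000

is the upper-tail p-value (reported as the plain proportion, so a
saturated test prints exactly P = 1). For small universes
`exhaustive_null` enumerates all placements exactly. Two near-fractions
can also be compared with the classic two-sample proportion test
(Pearson chi-square with Yates continuity correction).

## Worked example

Simulate a two-chromosome mini genome with breakage enrichment planted at
three "checked" origins, profile it, call sites, and test the origin
association:

```sh
fragilemap simulate --layout chrom.sizes --truth truth.yaml \
    --spacing 500 --seed 11 --out breakage.tsv
# wrote 800 probes to breakage.tsv
fragilemap profile --sample breakage.tsv --layout chrom.sizes \
    --window 6000 --out breakage.bedGraph
# profiled 792 probes (8 flagged removed, 0 dropped)
fragilemap sites breakage.bedGraph --out breakage.sites.bed
# 396 sites (above_median, threshold 0.7633) -> breakage.sites.bed
fragilemap associate --sites breakage.sites.bed \
    --features checked_origins.bed --category checked_origin \
    --probes breakage.tsv --layout chrom.sizes \
    --cutoff 6000 --sims 10000 --seed 17 --out assoc.json
# 71/396 sites within 6000 bp of a feature; P = 0 (10000 simulations)
```

Half of the 792 profiled probes exceed the median (396 sites, as the rule
implies); 71 of them fall within 6 kb of one of the three planted origins
versus ≈ 36 expected for random positions (9% of the genome is
origin-proximal), and none of the 10,000 random draws reached the
observed count, so P = 0 at this simulation depth. The proportion test
compares two such near-fractions directly, e.g. for 41.6% vs 11.7% of
639 sites:

```sh
fragilemap proptest 266 639 75 639
# p1 = 0.4163, p2 = 0.1174, X-squared = 144.3923, P = 2.916e-33
```

A whole configured analysis (several samples, several feature categories,
pairwise profile correlations, a per-category association table) runs
with `fragilemap run-all --config run.yaml`; see `fragilemap --help`.

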