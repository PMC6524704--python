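# Methods

## Scope and model

`pepkin` analyzes time-resolved peptidomics of complex mixtures by
spectral counting. The pipeline starts at *identified peptides* (a TSV of
peptide-spectrum observations); database search, FDR control of
identifications and any vendor formats are upstream and out of scope.
Its core assumption is that peptide utilization by a growing bacterial
culture is governed by global physicochemical properties rather than
exact sequence, so peptides can be pooled into physicochemical classes
whose summed spectral counts are dense enough for count statistics.

### Descriptors

Nine composition-based descriptors are computed per sequence: length,
GRAVY (mean Kyte–Doolittle hydropathy), bulkiness (mean Zimmerman
side-chain cross-section, Å²), polarity (mean Grantham polarity),
Henderson–Hasselbalch net charge, and the fractions of basic (K, R, H),
acidic (D, E), aromatic (F, W, Y) and proline residues. Scale tables ship
as editable plain-text files under `pepkin/data` and were validated
against all published reference barcodes.

Net charge is the **raw** (not length-normalized) sum of group charges at
the analysis pH (default 6.0), using the EMBOSS pKa set (C-term 3.6,
N-term 8.6, D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5) with both
termini included. Normalizing by length would be incompatible with the
published "> 1" upper interval and the printed reference class codes;
those codes are insensitive to the termini flag at pH 6 (the two terminus
contributions nearly cancel) and to His pKa within [6.0, 6.5].
Modification annotations in identification output (e.g. oxidized
methionine) are stripped and the plain residue is scored; modified and
plain forms of a sequence are merged.

### Barcoding

Each descriptor's range is split into three intervals; the class code
concatenates the nine interval digits in the order listed above. Default
cut points: length ≤ 9 / [10; 12] / ≥ 13; GRAVY ≤ −2 / ]−2; −0.5] /
> −0.5; bulkiness ≤ 12.6 / ]12.6; 14.7] / > 14.7; polarity ≤ 8.7 /
]8.7; 10.1] / > 10.1; net charge < 0 / [0; 1] / > 1; residue fractions
= 0 / ]0; 0.12] / > 0.12. Boundary closures are encoded exactly as
printed and compared at full floating precision — values extremely close
to a cut could in principle classify differently from a pipeline that
rounds before comparison. The scheme is data, not code: the cuts above
were chosen for one yeast-extract peptidome from its initial (t = 0)
property distributions, and other media or instruments should supply
their own cut points via the plain-text scheme format.

### Filtering

Two class-level filters precede testing. (1) Low abundance: a class
whose count is below 5 spectra in **every** sample is discarded
(max-over-samples reading; a total-count reading is available via
`abundance_mode="total"`). (2) Constancy: on per-timepoint means across
replicates, classes with (max − min) / min < 0.5 are set aside as
constant and reintegrated after profiling. A vanishing minimum with a
non-zero maximum counts as infinite variation (testable). Whether the
original analyses used (max − min) / min, (max − min) / max or max / min
is not determinable from published material; the first is used, with the
choice isolated in `variation_ratio`.

### Differential testing

Counts in each testable class are treated as independent Poisson
observations, replicates sharing a per-timepoint rate; time is the only
factor (no replicate or batch term — a deliberate match to the simplest
stated model; a quasi-Poisson switch divides the statistic by a Pearson
dispersion estimate for over-dispersed data). Poisson MLEs under both
the full (one rate per timepoint) and null (grand rate) models are group
means, so the deviance-difference LRT has the closed form
`2 Σ y log(μ̂_t/μ̂₀)` with zero-count terms contributing zero; no
iterative fit is needed, and equivalence with an iterative IRLS fit is
asserted to 1e-8 in the tests. The statistic is referred to χ² with
T − 1 degrees of freedom; all-zero classes get statistic 0, p 1.
Benjamini–Hochberg adjustment (step-up with monotonicity enforcement) is
applied across classes and significance is called at adjusted p ≤ 0.01
(inclusive boundary).

### Kinetic profiling

Published precedent assigns decreasing / increasing / fluctuating labels
manually. `pepkin` codifies that step: with ρ the Spearman rank
correlation between replicate-level counts and time, a significant class
is *decreasing* if ρ ≤ −0.5 and its last per-timepoint mean does not
exceed its first, *increasing* in the mirrored case, otherwise
*fluctuating*. The ±0.5 threshold is a declared convention (exposed as
`rho_threshold`), validated qualitatively against published exemplar
trajectories; near-threshold trajectories are genuinely ambiguous and no
quantitative criterion from the original manual step exists to recover.
Constant classes from the second filter are reintegrated with the label
`constant`. Profiles are characterized by Wilcoxon–Mann–Whitney (two
groups) or Kruskal–Wallis (more) tests per descriptor, and by a PCA of
the centred, unit-variance descriptors of the unique member peptides
(one point per peptide); zero-variance descriptors are dropped with a
warning (tolerance 1e-12 relative to the squared data scale).

## Synthetic-data design

The generator emulates the statistical structure this analysis assumes
for a yeast-extract peptidome, with known ground truth.

* **Pool**: 4,600 distinct peptides. Lengths are 6 + ⌊Gamma(5, 1)⌋
  truncated to [6, 30]: mode 10, median ≈ 10, mirroring a 3 kDa
  ultrafiltration upper bound and an m/z-driven lower bound of 6.
  Residues are i.i.d. per position (uniform by default;
  yeast-proteome-like frequencies available). Real peptides are proteome
  substrings, but all nine descriptors are order-invariant, so positional
  structure would be invisible downstream.
* **Abundance**: per-peptide base rates (expected spectra per sample)
  follow a two-component lognormal: bulk median 0.14 (σ = 0.8) plus a
  1.5% abundant component with median 2.5 (σ = 0.8). Calibrated once so
  a t = 0 sample reproduces the reference abundance structure after
  profile planting: ~72–76% of identified peptides carry one spectrum
  and well under 1% more than ten. A side effect of keeping that shape
  at the fixed pool size is ~900–1,000 identified peptides per sample,
  somewhat below the ~1,300–1,700 of the reference experiment.
* **Profiles**: planted at class level on the barcode structure the
  pipeline uses. Classes with net-charge digit 3 and length digit 1
  (short, positively charged — the transporter-substrate signature) are
  eligible *decreasing*; net-charge digit 1 with proline digit 3
  (negatively charged, proline-rich — accumulating protease products)
  eligible *increasing*. Twelve classes per profile (decreasing,
  increasing, fluctuating) are planted on the largest eligible classes;
  everything else is constant. Twelve per profile keeps recovery
  fractions statistically meaningful; profiled classes are the
  peptide-rich ones, as in the reference data.
* **Effect sizes**: decreasing rate × e^(−kt) with k = ln 4 / t_max
  (4-fold drop over the course); increasing mirrored; fluctuating a
  Gaussian pulse (×3 peak at t = 4 h, width 1 h). Planted classes are
  rescaled so their class rate at trajectory **peak** is lognormal
  (σ = 0.2) with medians 25 / 30 / 22 spectra per sample for
  decreasing / increasing / fluctuating — the scale of published
  exemplar trajectories, increasing richest per class. This reflects
  that a kinetic trend is only observable on classes abundant enough to
  quantify: a 4-fold effect on a class near the 5-spectra filter floor
  is statistically undetectable at FDR 0.01, in synthetic and real data
  alike.
* **Counts**: Poisson(base_rate × multiplier(t)), independent across
  replicates (3) and timepoints ({0, 3, 4, 5, 6} h); only non-zero
  counts are emitted (a zero-count peptide is simply not identified in
  that sample). Poisson by default so the differential model is
  correctly specified and recovery is a well-posed oracle; a
  negative-binomial switch (`nb_size`) probes overdispersion
  robustness. A fixed seed reproduces the emitted TSV byte-for-byte.

What passing the end-to-end tests therefore shows: the pipeline recovers
planted, well-specified, abundance-matched effects and controls its FDR
on truly constant classes. What it does not show: robustness to
overdispersed counts (probe with `nb_size`), to identification bias
correlated with physicochemistry, to missing replicates, or to any
dependence between abundance and class beyond the planted profiles —
real peptidomes may exhibit all of these.

## Numerical choices and degenerate inputs

* Interval assignment raises on NaN; ties at cut points follow the
  printed closures, never randomness.
* LRT terms with y = 0 contribute 0; an all-zero class returns
  statistic 0, p 1; a single timepoint is an error.
* BH adjustment is order-preserving and permutation-invariant; empty
  input returns empty output.
* `classify_profile` refuses constant input (the constancy filter must
  run first); identical-group rank tests return p ≈ 1 under tie
  correction.
* Aggregation is idempotent and conserves total spectra; classes with no
  counts in any retained sample are dropped.

## Limitations

* Class-level inference only: no peptide-level differential testing by
  design (single-spectrum peptides cannot support it).
* The interval scheme is descriptive, not data-driven; transferring the
  default cuts to another medium without inspecting its t = 0
  distributions is not recommended.
* Plain Poisson is the default model; strongly overdispersed spectral
  counts will inflate significance unless the quasi-Poisson switch is
  used.
* The profile labels near the ρ = ±0.5 threshold are a convention, not a
  recovered fact.
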