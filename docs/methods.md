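# Methods and modelling notes

This note records what the package computes, the assumptions behind the
synthetic-trial generator, the numerical conventions, and the design
choices that were genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Digestibility chain

All coefficients are apparent total-tract values from a nutrient mass
balance between feed intake and excreta. The chain per bird:

1. **Amounts.** Daily manure dry matter = ADM/1000 × DMW, where ADM is
   the air-dry recovery (g air-dried manure per kg fresh) and DMW the
   fresh daily manure weight (g/day, measured as total fresh manure over
   a 3.5-day collection window divided by 3.5). Daily feed dry matter =
   DFC × DM_feed/1000. Using ADM as a dry-matter measure implicitly
   assumes air-drying to constant weight; see the generator notes below.
2. **Bases.** Assay contents arrive on the air-dried-sample basis and are
   converted to g/kg DM via the sample's own DM content
   (content_dm = content_ad × 1000 / dm_ad). Feed contents arrive as-fed
   and are converted the same way via the feed DM. A configuration switch
   (`feed_is_dm_basis`) accepts feed contents already on a DM basis, as
   diet formulations are sometimes quoted that way.
3. **Nitrogen correction.** Avian excreta mix faeces and urine; urinary N
   is predominantly uric acid. Manure N is corrected as
   N_corr = N − f_UA × UA with f_UA = 4×14.007/168.11 ≈ 0.33328, the
   stoichiometric N fraction of uric acid (C₅H₄N₄O₃). The exact
   laboratory correction protocol behind published datasets is typically
   not disclosed; the stoichiometric constant is exposed as an argument
   (`ua_n_fraction`) so an alternative factor can be substituted.
4. **Organic matter** is defined as DM − ash on both the feed and the
   manure side (org content per kg DM = 1000 − ash content). No separate
   organic-matter assay is required.
5. **Flags, not clamps.** A DC may exceed no more than 100 by
   construction, but can legitimately be negative when excretion exceeds
   intake (measurement error, feed wastage); such birds are flagged
   `negative_dc` and retained. A bird with zero manure output gets DCs of
   100 with a `zero_manure` flag. Reported tables round to one decimal;
   all stored values are full precision.

## Feed-efficiency indicators

- Laying percentage LP = eggs laid / eggs expected × 100, with the
  expectation window (default 8 days) deliberately longer than the
  feed-recording period (default 7 days) because eggs laid just before
  the window can roll into the first collection.
- Egg mass EM = mean egg weight × LP/100 (g/day). FCR = DFC/EM, reported
  missing (NaN) for non-layers rather than infinite; such birds are
  flagged for the screening stage.
- RFC = observed feed − (b0 + b1·DBW + b2·EM + b3·BWG). The feed term is
  total feed over the recording period (g) by default with a per-day
  switch; published RFC means for this design are not reconstructible
  from line means, so the time basis genuinely cannot be verified from
  printed values and both are supported. Body-weight gain defaults to 0
  (adult hens over one week). The shipped b-coefficients are all zero —
  the null model — because real coefficients are environment-specific
  and, for the motivating dataset, confidential; users must supply their
  own via `rfc_coefficients` in the config.

## Synthetic-trial generator

The generator emulates a two-line, individually housed layer trial at the
end of lay (90–96 weeks) on a single corn–wheat diet (900 g DM, 25 g N,
50 g fat, 131 g ash, 38 g sugar per kg as-fed).

**Draws per bird.** DFC, DBW and egg weights are truncated normals; egg
laying is Bernoulli per day over the 8-day window; the latent DC vector
(DM, fat, N, org) is multivariate normal truncated to [0, 100] *and* to
the mass-balance-feasible region (below). Randomness derives from one
seed through per-line, per-bird seed-sequence substreams, so enlarging a
line appends birds without perturbing existing ones.

**Mass balance.** Excreted mass = intake × (1 − DC/100) independently for
DM, fat, faecal N and organic matter. Manure ash is the balancing residue
excreted DM − excreted organic matter — the exact inverse of the
pipeline's org = DM − ash definition — so all four latent DCs are free
parameters and are recovered exactly (machine precision) when assay noise
is zero. This is the repository's central oracle. Treating ash as the
residue rather than as fully indigestible was a deliberate choice: full
ash excretion would tie DC_DM to DC_Org through the diet's ash fraction
and make independent latent values unrecoverable. At the default line
means the implied manure ash is ≈ 24–25 % of manure DM, a realistic
figure for laying hens excreting surplus minerals and calcium.

**Feasibility truncation.** Not every DC vector is physical: a DC_Org far
below DC_DM would imply more organic matter than dry matter in excreta.
Draws are rejected until the vector satisfies excreted org/fat/N ≤
excreted DM; if the feasible region holds negligible probability the
generator raises instead of silently distorting the distribution. At the
default parameters the rejection rate is small and the induced mean shift
is far below one printed SE (the parameter-recovery test measures this
end to end).

**Latent DC correlation.** The four DCs of one bird are biologically
coherent — reported within-line correlations reach 0.92–0.95 between
DC_DM and DC_Org — and at the study's between-bird SDs near-independent
draws would constantly hit the feasibility boundary. The default
correlation matrix therefore couples DM–Org at 0.95, DM–N and N–Org at
0.7, and fat to the rest at 0.4–0.5; `dc_correlation=None` gives
independent draws for users exploring other regimes.

**Urinary nitrogen.** A configurable fraction (default 0.35) of total
excreted N is bound in uric acid; the corresponding uric-acid mass is
placed in the assay so the pipeline's stoichiometric correction removes
exactly the urinary share. The default is a mid-range literature figure
for hens in positive protein balance; with it, simulated manure uric-acid
contents land in the tens of g/kg DM, as observed in practice.

**Moisture and air-drying.** Fresh manure weight = excreted DM /
(1 − moisture fraction). Line moistures (0.733 and 0.740) are set so that
the expected DMW at the line means matches the observed line means
(121.6 and 146.6 g/day). The air-dried sample's DM content defaults to
1000 g/kg (drying to constant weight), which makes the ADM-based Eq.-(4)
conversion exact; setting `airdry_dm` below 1000 reproduces the small
known bias that residual moisture induces when ADM is used as a DM
measure, scaling every amount-based DC term by 1000/dm_ad.

**Assay noise.** Multiplicative, mean-one lognormal with CV
`assay_noise_cv` (default 0.02, a typical within-lab analytical CV),
applied to ADM and the four analyte contents but not to the air-dried
sample's DM content (perturbing a value capped at 1000 g/kg would bias it
downward and all contents upward).

**Default line parameters** are the published two-line means: DFC
142.0/122.8 g, DBW 1718/1683 g, LP 82/92 %, DC_DM 74.6/65.5, DC_Fat
86.0/78.8, DC_N 77.5/73.5, DC_Org 77.5/69.8 % for lines A/B. Between-bird
SDs are reconstructed from printed SEs as SE×√n with n = 43/44 (the
group sizes behind those SEs); mean egg weights are EM/LP×100
(≈ 60.1/58.5 g) with a 5 g SD, a typical within-flock spread. Egg-laying
is an independent Bernoulli per day — the generator has no between-day
autocorrelation, no aging, no feed-wastage behaviour and no line-by-diet
interaction, so passing tests validate the estimation chain and the
statistics, not those biological dynamics.

## Statistical stages

- **Outlier screening** uses Tukey fences per line: a record is removed
  whole if any screened trait lies outside [Q1 − k·IQR, Q3 + k·IQR],
  k = 1.5, quartiles by linear interpolation, computed once on the
  incoming data (not iterated). The default screen covers DFC, EM, DMW,
  DBW, FCR and the four DCs; missing values never trigger removal. The
  filter-audit test injects displacements into a single trait and screens
  that trait, because on ~9 jointly screened Gaussian traits a 50-bird
  line flags a few natural fence-outliers and the audit would not isolate
  the injections.
- **Between-line tests** are Welch (unequal-variance) two-sample t-tests
  by default — the safer default when line variances differ, as the
  default simulation's do — with the pooled variant behind a flag.
  Zero-variance equal groups report t = 0, p = 1 by convention.
- **Correlations** are pairwise-complete Pearson r with t-distribution
  p-values, masked at α = 0.05 (constant traits masked as undefined).
  No multiple-testing correction anywhere, matching standard practice for
  this design.
- **PCA** centers and (by default) unit-scales the trait table — the
  traits mix grams, percent and ratios — and decomposes via SVD;
  explained-variance percentages sum to 100 over retained dimensions and
  per-trait contributions are squared loadings × 100. The variable set is
  the five performance traits plus the four DCs, per line; FCR and RFC
  are excluded as derived traits. Unscaled mode is available.
- **Prediction models** are OLS: FCR or RFC on EM + DBW (performance
  model; DFC and LP excluded because they are arithmetically confounded
  with the response), and FCR or RFC on a single DC at a time (DC_DM,
  DC_N or DC_Org) because the DCs are strongly mutually correlated.
  In-sample R² only; no cross-validation.
- Rendered tables band p-values at <0.1, <0.05, <0.01, <0.001.

## Numerical conventions and problem sizes

CSV output uses `%.17g` floats and reading uses round-trip parsing, so
write→read is lossless. Truncated-normal draws use rejection sampling
(falling back, with a warning, to the clipped mean after 1000 tries).
The Monte-Carlo validations run at the sizes a laptop handles in seconds:
the parameter-recovery check uses 200 replicate trials of 43 + 44 birds,
the Welch calibration 2000 null replicates, convergence checks one line
of 10⁴ birds.

## Known limitations

- The uric-acid correction is purely stoichiometric; lab protocols that
  correct with ammonium or creatinine terms will differ slightly.
- RFC is only as meaningful as the supplied b-coefficients; the null
  default makes RFC equal observed feed consumption.
- The generator draws traits independently across birds and (apart from
  the latent DC correlation) across traits, so realized trait–trait
  correlations such as DFC-with-DC are near zero by construction; the
  prediction-model stage is validated on its own synthetic fixtures, not
  on the trial generator.
- Exactly two lines are required for the t-test stage; other stages work
  per line for any number of lines.
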