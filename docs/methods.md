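# Methods

## The enrichment-factor statistic

For one taxon in one substrate × timepoint cell, with relative read
abundances in the sequenced heavy and light fractions of the ¹³C gradient
and its paired ¹²C control,

EF = ¹³Cheavy/¹³Clight − ¹²Cheavy/¹²Clight.

Subtracting the control ratio removes the taxon's intrinsic banding
behaviour (GC content shifts rRNA density even without label), so an EF
near 0 is the no-assimilation expectation regardless of the taxon's
abundance profile. The statistic is a relative labeling indicator, not a
quantitative atom-fraction estimate: gradients are unreplicated, and no
density-shift model is fitted to read distributions across all fractions.

Decision rules, with defaults:

* **Abundance filter** — EFs are reported only for taxa whose heavy-fraction
  relative abundance in a ¹³C gradient strictly exceeds 2% in at least one
  cell, to avoid over-interpreting ratios built from a handful of reads.
  Protist taxa are exempt (they are analyzed regardless of abundance, as
  their libraries are shallow and their taxa rare). Normalization is over
  all reads in the fraction; the filter is applied after normalization.
* **Labeling call** — a taxon is ¹³C-labeled if any of its EFs strictly
  exceeds 0.5, across all treatments and timepoints. The call is a property
  of the taxon; per-cell marks in the overview matrix are `+` (EF > 0.5 in
  that cell) and `++` (additionally ≥10% heavy-fraction abundance — the
  "markedly labeled" tier; the 10% cut is this package's choice and is
  configurable).
* **Display value** — for plotting on a log₁₀ axis, a labeled taxon's EF is
  shown as log₁₀(EF), floored at −1.5; cells with non-positive EF of a
  taxon labeled elsewhere are pinned to −1.5 so they remain visible.
* **Pseudocount** — the ratio in EF is undefined when a taxon has zero reads
  in a light fraction. The default policy adds a pseudocount of 1 to every
  taxon's count in every sequenced fraction before normalization: ratios
  stay bounded and orderings are preserved. Setting the pseudocount to 0
  disables this and makes zero denominators an explicit error. Scale
  invariance of the EF under global count rescaling holds exactly at
  pseudocount 0 and approximately otherwise.
* **Pairing** — each ¹³C gradient is compared with the ¹²C control of the
  same substrate and timepoint; one control table per cell. Taxa present in
  the ¹³C table but absent from the control are treated as zero-count there
  (then pseudocounted).

## The two-pool mixing model

% substrate-derived C = (δ_sample − δ_reference)/(δ_substrate − δ_soil) × 100,
all δ values in ‰ vs. VPDB. δ_reference is the mean δ¹³C of unamended
control replicates at the **matching pool and timepoint** (matching absorbs
temporal drift of the background signature; the alternative — one grand
control mean — is a one-line change). The model assumes exactly two
end-members with fixed signatures and linear mass balance; it therefore
inverts the simulator's generative model exactly when noise is zero.
Estimates outside [0, 100]% are flagged (`out_of_range`), never clipped:
out-of-range values diagnose noise, drift or wrong end-members.

PLFA pool signatures are concentration-weighted means over marker sets;
defaults are bacterial {i15:0, a15:0, i16:0, 16:1ω7, 18:1ω7, cy17:0,
cy19:0} and fungal {18:2ω6,9}. The fungal marker also occurs in plant
tissue, so pooled values for plant-biomass treatments carry a caveat flag
and a warning. Microbial biomass carbon is accepted as an input pool
(δ¹³C + mass), not recomputed from fumigation-extraction raw data.

Carbon-budget helpers: cumulative mineralization as a percent of added C
(with a non-decreasing integrity check) and amendment normalization
(mg C per microcosm → µg C g⁻¹ soil).

## The gradient simulator

The simulator generates the inputs the analysis assumes, with known ground
truth:

* **Density model.** A taxon with labeled rRNA proportion *a* bands as a
  two-component Gaussian mixture: mass 1−*a* at N(ρ_u, σ), mass *a* at
  N(ρ_u + Δρ, σ). Defaults ρ_u = 1.790 g ml⁻¹, Δρ = 0.035 g ml⁻¹,
  σ = 0.008 g ml⁻¹, 12 equal bins spanning 1.755–1.845 g ml⁻¹, which puts
  the unlabeled mode in fraction 8 (light, ~1.79) and the fully labeled
  mode in fraction 3 (heavy, ~1.82), with fraction 1 the densest. The
  two-population form reflects that rRNA made from a uniformly labeled
  substrate is near-fully labeled while legacy rRNA is not. Defaults are
  literature-typical for CsTFA rRNA gradients, not fitted to any dataset.
  Mass outside the binned range (gradient flow-through) is truncated and
  weights renormalized.
* **Read sampling.** Expected composition of fraction *f* is
  baseline_i · w_if / Σ_j baseline_j · w_jf; observed counts are multinomial
  at fixed depth (default 10,000 reads per fraction), so sequencing depth is
  compositional — a fraction with almost no RNA still yields full read
  depth, as amplicon libraries do.
* **Default community.** Twelve taxa (bacteria, fungi, one protist) with
  uneven baselines (4–14%); per substrate and timepoint a few taxa carry
  labeled-rRNA proportions of 0.3–0.8, the rest 0. This emulates the
  qualitative picture of a detritusphere experiment: a handful of dominant
  primary consumers against an unlabeled background.
* **δ¹³C series.** δ_sample = δ_ref + f·(δ_sub − δ_soil) + N(0, 0.5‰),
  three replicates per cell; the default scenario is a C3 soil (−26.5‰)
  with a C4-derived amendment (−12‰), a ~14.5‰ contrast.
* **Determinism.** One RNG per simulate call, seeded from the config; the
  seed is echoed into sidecar metadata, and a fixed seed reproduces every
  output byte-for-byte.

What the simulator does **not** model: PCR/primer bias, chimeras, taxonomic
misassignment, raw reads (it starts at the taxon-count level), per-domain
library splits (16S vs 18S), compositional coupling between gradients, or
gradient-to-gradient density calibration drift. Passing recovery tests
therefore demonstrates correctness of the inference pipeline given the
banding model, not robustness to those real-data artifacts.

### Calibration properties

With 20 equally abundant (5%), fully unlabeled taxa at depth 10,000, |EF|
stays below 0.2 in ≥95% of taxon × seed cases (multinomial noise alone);
taxa with labeled proportion ≥0.5 and baseline ≥2% are called labeled in
≥95% of simulations. Both properties are recomputed by
`scripts/acceptance.py` over 100 fresh seeds (seconds of CPU).

## In-silico T-RF prediction

A T-RF is the fragment from the 5′ end of the labeled forward primer to the
first restriction cut. The digester anchors the primer at its 5′-most
alignment within a mismatch budget (default 0), truncates there, and scans
for the first IUPAC-compatible occurrence of the enzyme's recognition site;
the cut position is the site index plus the enzyme's cut offset (MspI =
C^CGG → offset 1). Sequences without an anchorable primer are reported
`unanchored`; without a downstream site, `uncut` with the full remaining
length. Only forward-strand fragments are reported (single-labeled-primer
T-RFLP). Matching against observed fragment sizes uses ±2 bp by default,
a typical capillary sizing error. The site scan is implemented by regex
expansion of IUPAC codes and verified in tests against an exhaustive
position-by-position set-membership scan. A small registry of common
T-RFLP enzymes ships as examples; any recognition sequence + cut offset is
accepted.

## Pipeline and numerical choices

`run_pipeline` executes simulate → enrichment → mixing → T-RF and writes
all stage tables, a JSON report and a Markdown report; input gradient TSVs
are validated up front (schema, non-negative counts, densities strictly
decreasing with fraction number, complete ¹³C/¹²C pairing) with all
violations collected and reported at once. Default analysis profile:
heavy = fraction 3, light = fraction 8, abundance threshold 2%, EF
threshold 0.5, pseudocount 1; all thresholds live in `RunConfig` alone and
are echoed into the report. Thresholds are strict inequalities. Degenerate
inputs fail loudly: empty fractions, equal mixing end-members, decreasing
cumulative CO₂ series and missing PLFA markers all raise with the offending
identifier.

Problem sizes used in the shipped tests and acceptance script — 100 seeds,
depth 10,000, 20-taxon null community, 1,000 random sequences for the
digestion oracle — keep full recomputation in the seconds-to-minutes range
while leaving Monte-Carlo margins comfortably away from the pass/fail
boundaries.

## Known limitations

EFs from unreplicated gradients carry no variance estimate; the labeling
call is a threshold rule, not a test. The simulator's truncation of
flow-through mass slightly redistributes extreme-density tails. The "++"
tier threshold (10% heavy abundance) is a display convention. Real
experiments with very uneven sequencing depth between heavy and light
fractions are handled only through the compositional (relative-abundance)
formulation; absolute rRNA quantities per fraction are not modeled.
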