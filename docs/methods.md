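# Methods

## Model

The assay quantifies species composition of a powdered plant mixture from
allele frequencies at diagnostic SNPs. Its core assumption is **equal
yield**: every amplifying species contributes amplifiable template DNA in
proportion to its mass, with the same proportionality constant. Under that
assumption the pyrosequencing frequency of an allele carried by a set of
species equals those species' share of the total amplifying mass:

    r(site, allele) = Σ m_s · y_s  (s carrying the allele)
                      ─────────────────────────────────────
                      Σ m_s · y_s  (all amplifying s)

with masses `m_s` in grams and yield factors `y_s = 1` by default.
Non-amplifying impurities (soil, flour, processed excipients) appear in
neither sum: they are invisible to the assay, so every reported total is
the *amplifying* mass, not the physical sample weight.

Quantification inverts this relation with an **external standard**: a known
mass `w_ext` of a species absent from the sample is mixed in. Its species-
diagnostic allele frequency `r_ext` can then only come from the spike, so

    w_total = w_ext / r_ext                 (step 1)
    w_i     = w_total · r_i                 (step 2)

for every identified component *i*. Substituting `r_ext` into step 2
returns `w_ext` exactly — an algebraic identity the tests exploit — and
multiplying all masses by a constant leaves every frequency, hence the
relative errors, unchanged (scale equivariance). Results are accepted when
the relative bias |calculated − actual|/actual is below 25 %.

Frequencies enter the two steps raw. An optional correction maps measured
frequencies through the inverse of a fitted standard curve
(`x = (y − b)/a`) before the mass math; it is off by default because the
assay's reference calculations use raw frequencies and the fitted response
is within a percent of identity anyway.

## Screening

A **group-diagnostic** site is an alignment column where every sequence of
the target group carries one fixed unambiguous base and every adulterant
sequence a different fixed unambiguous base; a **species-diagnostic** site
is the same predicate for one adulterant taxon against everything else.
Design choices, where the underlying assay description leaves room:

- *Fixedness policy*: any gap or IUPAC ambiguity code in any considered
  sequence disqualifies the column. Conservative; zero discordant
  accessions are tolerated per species.
- *Species-site background*: the complement must be fixed for a single
  alternative base (all reference examples have exactly one background
  genotype). `require_fixed_background=False` relaxes this to "background
  merely lacks the taxon's base" for exploratory screens.
- *Joint taxa*: adulterant species that no column separates individually
  (here *F. pallidiflora* + *F. walujewii*, "FPB") are screened as a named
  union and share one site; the panel's coverage map points both members at
  it. Such a site detects and weighs the pair, not either member alone.
- *A-base ranking*: pyrosequencing dispenses nucleotides stepwise and base
  A consumes extra substrate, distorting quantitative peaks, so candidate
  group sites whose alleles avoid A rank first (ties: support descending,
  then position ascending). Species sites are unique identifiers used for
  presence calls first and quantification only of typed components, so the
  A-penalty is waived for them, matching assay practice.
- *Flanks*: exported context (default 55 nt, site-centred) is cut from one
  designated representative accession, never a consensus, because external
  BLAST verification must use a real sequence. Truncation at sequence ends
  is flagged rather than padded.
- *Coordinates*: positions are 1-based columns of the input alignment. The
  published positions of any real assay may instead be coordinates on a
  reference accession; reports therefore always carry the alignment file
  name alongside positions.

## Simulator

`MixtureSpec` defines the ground truth (masses, impurity mass, yield
factors, noise, distortion, seed). Observed target-allele frequency per
replicate is

    obs = clamp(a · r_expected + b + ε, 0, 1),   ε ~ N(0, noise_sd²)

with the background allele mirrored as `1 − obs`, so biallelic frequencies
sum to 1 exactly. Defaults and why:

- `distortion = (0.994, 0.002)` — the fitted frequency response of the
  instrument assay this package models; near identity, so it perturbs
  recovered masses by well under 1 %.
- `noise_sd = 0.005` (absolute, on [0, 1]) — chosen once so the simulator
  reproduces the assay's validated working floor: at 1 % adulteration the
  true replicate CV is 0.005/0.0119 ≈ 42 % (hopeless), at 2 % it is
  0.005/0.0219 ≈ 22.9 % (just under the 25 % LOQ bound). The 2 % level is
  thus deliberately near the boundary: single 20-replicate studies land on
  either side with non-trivial probability, which is how such assays behave
  in practice; the calibration claim is about the expectation, and the
  tests check it with a high-replicate study plus a majority vote over many
  20-replicate studies.
- Noise is Gaussian and homoscedastic because only replicate RSDs, not a
  noise law, are available to calibrate against; clamping at the unit
  interval stands in for the instrument's bounded output.

What the simulator does **not** emulate: pyrogram peak traces and
dispensation chemistry (the exported allele frequency is the level all
downstream math consumes), PCR amplification bias, copy-number variation
between species, and DNA fragmentation in processed products. Yield
factors other than 1 exist purely for sensitivity analysis — they break
the equal-yield assumption that makes the mass math valid, and passing
tests under default yields say nothing about real mixtures where yields
differ.

Synthetic alignments plant specified diagnostic columns into random
background columns that are rejection-sampled against *every* diagnostic
predicate, so planted-site recovery is exact by construction and screening
can be tested for both false negatives and false positives.

## Validation rules

- Repeatability: mean and RSD per level, with the **sample** (n−1)
  standard deviation — the convention is load-bearing, as the reference
  replicate tables reproduce only under ddof = 1.
- LOD: lowest level with detection rate ≥ 0.95 whose higher tested levels
  all pass too (stability clause). "Detected" means the adulterant
  allele's measured frequency reaches the detection threshold, default
  0.01 — deliberately below the 0.02 quantification presence threshold so
  detection saturates before quantification becomes reliable. Fewer than
  20 replicates per level triggers a warning, not an error.
- LOQ: lowest level with RSD ≤ 25 %, same stability clause. LOD and LOQ
  are independent criteria; no ordering between them is assumed.
- Linearity: OLS of mean frequency on level; gate R² ≥ 0.99; at least
  three distinct levels required, otherwise the report marks linearity
  (and LOD/LOQ where undefined) as unavailable rather than failing.

## Quantification workflow details

- Replicates are aggregated by arithmetic mean per site before any mass
  math.
- Presence calls use threshold 0.02 (the validated LOD/LOQ); a site call
  is pure-target, pure-background or mixed. Composition logic: a pure
  target-group call means no adulteration; a mixed or pure-background group
  call plus positive species sites identifies the adulterants; adulterant
  signal with no positive (or missing) species site leaves the composition
  **unresolved**, and quantification is refused instead of silently
  attributing untyped mass. The external standard is selected as the first
  candidate species absent from the sample.
- The frequencies of all identified components (standard included) should
  sum to 1; a deviation beyond ±0.05 emits a consistency warning (not an
  error — reference assays themselves print component percentages summing
  to 103 % due to display rounding).
- Masses are kept at full precision internally and rounded to 4 decimals
  (g), frequencies to whole percent, only in reports.

## Degenerate inputs and numerical choices

`r_ext = 0` raises an unquantifiable-sample error (the spike did not
amplify); frequencies outside [0, 1] are rejected at the measurement
boundary; mixtures with no amplifying mass, standard curves with fewer
than three distinct proportions, and empty dilution series are all
explicit errors. Measurement TSVs are written with `%.17g` and read with
round-trip float parsing so simulated data survive serialisation bit-for-
bit, which the determinism contract (same seed → identical files) relies
on.

## Problem sizes

The shipped test suite and reproduction script run on synthetic data at
desk scale: alignments up to ~30 taxa × 1200 columns, dilution studies at
1–50 % adulteration with 3–500 replicates per level, and 1000-seed
round-trip studies at 6 replicates — sizes chosen to exercise every
decision rule while keeping the whole suite in the seconds-to-minutes
range.

## Known limitations

Equal yield is assumed, not estimated; differential DNA yield or ribosomal
copy number between species biases masses proportionally and is out of
scope. Only amplifying mass is estimable — the method cannot see soil,
flour or other non-amplifying diluents. Joint taxa are quantified as a
unit. The simulator's noise model is a calibration choice, surfaced in
`MixtureSpec`, not a measured instrument property; conclusions drawn from
simulated studies transfer to real instruments only insofar as that model
holds.
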