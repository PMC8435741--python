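# Methods

This note documents the models, conventions and design decisions behind
`rareg`, in the order the pipeline uses them.

## Registry model and multi-source merge

A registry holds four tables: patients, sibships, a disease catalogue
(inheritance mode AD/AR/XL and a six-level medical-specialty group), and
region demography (total / male / female / child population and district
count).  Patients carry three age bands — child (0–17 inclusive),
reproductive (18–45), post-reproductive (46+) — a non-empty set of
registration sources, and a proband flag.

`merge_sources` implements multiple registration: the same person may be
reported by several channels and must appear once.  Identity is a
configurable composite key, by default *(normalized name, birth year,
region)* — case-folded with whitespace collapsed, no phonetic or fuzzy
matching.  Records that share an identity but disagree on the disease are
*conflicts*: they are excluded from the merged patient table and itemized,
because resolving them is a clinical re-examination task, not a data
operation.  The merge is idempotent, and unique identities always equal
merged patients plus conflicts.

The familial-case rate counts patients whose family contains at least two
cases of the *same* disease; a sole case of its disease in a family is
sporadic/non-familial regardless of inheritance mode.

## Weinberg proband segregation analysis

Sibships reach a survey only through probands, so the naive affected
fraction overestimates the segregation frequency.  Under multiple
incomplete ascertainment — every affected child is independently
registered (is a proband) with probability π — the Weinberg proband
estimator

p̂ = Σ_f b_f (a_f − 1) / Σ_f b_f (s_f − 1)

is unbiased for the segregation frequency p whatever π is: each proband
contributes its sibship with itself removed, which restores a simple
binomial sample.  Implementation choices:

* standard error `sqrt(p̂(1−p̂)/Σ b(s−1))` — the binomial approximation
  treating the effective denominator as the number of informative sibs;
  a documented convention, not a calibrated quantity;
* two-sided z-test of p̂ against the Mendelian expectation (0.25 AR,
  0.5 AD) when requested;
* sibships of size 1 are accepted and contribute nothing (s − 1 = 0);
  a sibship with b = 0 is a contract violation (not ascertained) and
  raises; a denominator of zero (all size-1 sibships) raises.

The π-invariance of the estimator is the key property test: across 200
simulated replicates of 2,000 sibships each, the mean estimate stays
within ±0.01 of the generating p for π ∈ {0.3, 0.83, 1.0}.

## Registration-probability MLE

Given affected counts a_f, the proband counts b_f of ascertained families
follow a zero-truncated binomial law
`P(b|a) = C(a,b) π^b (1−π)^(a−b) / (1 − (1−π)^a)`.  π is estimated by
bounded scalar maximization of the log-likelihood on [1e-6, 1] with
tolerance 1e-8.  Families with a_f = 1 are excluded (they show b = 1 for
every π; their number is reported), and a dataset consisting only of such
families raises an explicit unidentifiability error.  When every
informative family has b = a the optimum is the boundary and π̂ = 1 is
returned directly.  The optimizer is verified against an exhaustive grid
search (step 1e-4) to within 2e-4 on small datasets.

X-linked sibships are excluded from `segregation_report`: male-limited
segregation in carrier sibships does not satisfy the autosomal proband
model.

## Prevalence estimation and tables

* **Rounding.** Rates per 100,000 are rounded half-away-from-zero to two
  decimals; the "1:N" form is the denominator over the case count rounded
  to the nearest integer.  This pair of rules reproduces every headline
  figure of the reference survey simultaneously (277.21, 558.71, 17.45,
  1:361, 1:2,109 …).
* **Class scheme.** Seven point-prevalence classes with clean half-open
  boundaries at 1:50,000, 1:100,000, 1:200,000, 1:300,000, 1:400,000 and
  1:500,000; an exact boundary rate belongs to the more frequent class;
  zero counts fall in the rarest class.  Binning compares integer cross
  products (`count × threshold ≥ denominator`), so boundaries are exact.
* **X-linked denominators.**  Rate columns use the conventional
  half-population male denominator (male_fraction = 0.5), which is the
  convention that reproduces the published X-linked rates (12.21, 6.70,
  4.21, 2.97, 2.75); the observed male share (≈0.464) is available as an
  option.  Class binning of XL diseases instead uses the census male
  population from the demography table: integer feasibility analysis of
  the published class cells shows they are consistent with the actual
  male population and not with the total population, matching the stated
  male-referenced treatment of X-linked pathology.
* **Tables.** The class table (patients and diseases per class ×
  inheritance), specialty table (patients, share, rate, diseases per
  specialty group) and region table (per-region counts with min/max
  district "1:N", district denominators being the region population split
  evenly across districts) all conserve totals by construction and are
  tested against independent full scans.

## Surname isonymy

Random isonymy is the plug-in estimator `I = Σ p_i²`; the unbiased
without-replacement variant `Σ n_i(n_i−1)/(n(n−1))` is available behind a
flag.  The random inbreeding component is F_r = I/4.  Surnames are pooled
(no marital-pair decomposition).  The module is validated by its closed
forms: one surname gives F_r = 0.25, k equally frequent surnames give
1/(4k).

## Synthetic-data generator

The simulator emulates the statistical structure of a multi-region
survey; it is the ground-truth source for every downstream test.

**Sibship generator** (`simulate_sibships`) — the generative model used to
validate the estimators: sizes from a zero-truncated Poisson (default
λ = 2.5 — a simple one-parameter positive-support choice; the surveys
report no sibship-size distribution), affection Bernoulli(p) per child,
proband status Bernoulli(π) per affected, observation conditional on
b ≥ 1.  The observed ascertained fraction is tested against exhaustive
(s, a) enumeration.

**Population simulator** (`simulate_population`) — true cases are placed
per (disease, region) as Poisson counts at the configured rate (expected
counts below 1 are flagged, not fatal).  A configurable
`familial_fraction` of each disease's cases is grouped into same-family
clusters of 2–3; this layer is *target-driven*, chosen so the observed
familial-case rate is directly controllable, and is therefore not a
Mendelian sampling process — estimator validation always uses the sibship
generator.  Each case is registered with its inheritance mode's π and
reported by each source independently with that source's sensitivity; a
case reported by no source is truly unobserved.  Emitted sibships carry
the true affected count and the registered proband count, so the
ascertainment MLE applied to them recovers the *effective* registration
probability π·P(≥1 source).  XL cases are male (X-linked recessive
convention; XL-dominant entries are out of simulator scope).

Defaults (the study conditions): segregation frequencies 0.5/0.25/0.5
(AD/AR/XL-in-sons); registration probabilities 0.72 (AD) and 0.83 (AR —
also adopted for XL, as the recessive-group value); familial fractions
0.75/0.30/0.175, the midpoints of the reported 70–80%, 26–34% and 15–20%
ranges; patient age-band shares 0.433/0.372/0.195; three sources with
sensitivities 0.85/0.70/0.55, chosen so ≈80% of observed cases are
registered by more than one source.  Randomness comes from one seed with
per-stage substreams derived via `numpy.random.SeedSequence`; identical
(config, seed) pairs produce byte-identical registries.

What the simulator does **not** model: mutation-level genetics, founder
effects, consanguinity, migration or drift, XL-dominant inheritance,
age-dependent onset or mortality, or correlated source sensitivities.
Passing recovery tests therefore show the estimators are correct under
the stated ascertainment model, not that real registries satisfy it.

## Synthetic reference registry

`make_reference_registry` builds a registry whose *marginals* match the
published survey exactly: 10,265 patients, 554 diseases, population
3,703,018 (764,260 children, 1,716,298 men), 4,270 child patients, the
per-class × inheritance cell counts, the per-specialty patient and
disease totals, and per-region patient quotas.  Everything below the
marginals — per-disease counts beyond the published frequent-disease
rows, specialty assignment of unnamed diseases, region/sex/age/district
splits, identities — is synthetic and deterministically allocated
(proportional quotas with largest-remainder rounding, northwest-corner
assignment of patients to regions, evenly spread age flags).

Published figures that are internally inconsistent were reconciled in
favour of the headline totals:

* regional patient counts sum to 10,752, not 10,265 — region quotas are
  rescaled proportionally;
* regional populations sum to 3,703,386, not 3,703,018 — the largest
  region absorbs the 368 difference;
* regional child populations sum to 800,123, not 764,260 — one region's
  child count (printed as a duplicate of another region's) is corrected
  so the total is exact;
* men + women exceed the total population by 367 — the male count is kept
  and the female count is the complement;
* the recessive frequent-disease rows sum to 2,154 while the class cell
  says 2,253 — the cell total wins and the residual goes to the largest
  unnamed-capacity row, never to the showcase rows whose published counts
  anchor rate checks;
* one dominant class cell (214 patients across 22 diseases) is integer
  infeasible under clean binning (each disease in that class needs 10–12
  patients); one disease is moved to the neighbouring class, leaving
  every patient total and both headline disease totals (33 and 350)
  unchanged;
* a handful of published frequent-disease counts (e.g. 72 patients listed
  in the ≥1:50,000 block) fall outside their block's count range under
  exact binning; they are clipped to the nearest in-range count so the
  rebuilt table bins cleanly.

The specialty layer must satisfy disease quotas *and* patient quotas at
once; a greedy assignment tracks each specialty's remaining
patients-per-disease ratio, and a repair pass moves patients between
same-cell diseases (and swaps labels between same-cell synthetic
diseases) until every specialty total is exact.  Feasibility is
guaranteed by the slack in the rarest class (350 diseases of 1–7
patients) and the unbounded most-frequent class.

## Problem sizes

The test suite and the acceptance script use 20,000-family sibship
cohorts for parameter recovery (recovery tolerances ±0.01 on p, ±0.02 on
π), 200 replicates of 2,000 families for the π-invariance property, and a
three-region / twelve-disease population configuration (~1,000 true
cases) for registry-level checks.  These sizes put Monte-Carlo error well
inside the stated tolerances while keeping the whole suite under a
minute.

## Known limitations

* The registration-probability estimator assumes independent proband
  registration within families; clustered reporting (one source covering
  a whole family) would bias π̂ upward.
* The published per-family data behind the survey's own 83%/72%
  registration probabilities are not available; those figures are
  validated by parameter recovery on simulation, not by reproduction.
* No confidence intervals on prevalence rates and no incidence
  estimation (the surveys report neither); no age standardization.
* The reference registry is a marginal reconstruction: joint
  distributions (e.g. disease × region) are synthetic, so only
  marginal-level figures should be read from it.
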