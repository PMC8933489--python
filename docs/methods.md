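# Methods

This note documents the models behind `retwatch`, the parameters that matter,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## CCF model

A somatic mutation present in a fraction *ccf* of tumor cells, at multiplicity
*m* mutant copies per carrying cell, in a sample of purity ρ whose locus has
total copy number *t* in tumor cells (and 2 in admixed normal cells), has
expected variant allele fraction

    v(ccf) = ρ·m·ccf / (ρ·t + 2·(1 − ρ)).

The observed alt count is modelled Binomial(depth, v(ccf)). The CCF likelihood
is evaluated on the grid {0.01, 0.02, …, 1.00}; the grid starts at 0.01
because a mutation observed at all has nonzero CCF, which avoids degenerate
zero-likelihood handling. Resolution is therefore 0.01 and estimates are
reported at that precision.

**Multiplicity.** m is the rounded mutant-copy estimate
`clip(round(maf·D/ρ), 1, t)` with `D = ρ·t + 2(1 − ρ)`, the standard choice in
allele-specific CCF annotation. A pure per-m likelihood scan is degenerate at
the clonal boundary: when sampling noise pushes the observed MAF above the
m = 1 ceiling `ρ/D`, m = 2 with ccf ≈ 0.5 attains strictly higher likelihood
and roughly half of all truly clonal mutations would be mis-assigned
ccf ≈ 0.5. The rounded estimator has no such instability and agrees with the
likelihood scan away from the boundary.

**Interval.** The grid-normalised likelihood is treated as a posterior under a
uniform prior, and the 95% interval is the *highest-posterior-density* (HPD)
set — the smallest collection of grid points reaching 0.95 mass (contiguous,
since the posterior is unimodal). An equal-tailed central interval was
evaluated and rejected: for truncal mutations the truncation-renormalised
97.5% quantile falls below 1.0 whenever the observed MAF is mildly below its
expectation, which drops boundary coverage to ~86% (~95% for the HPD set,
measured at duplex-era tissue depths of 200×).

**Rules.** Clonal ⇔ interval upper bound strictly > 0.85. Heterogeneous
sample ⇔ strictly more than 30% of non-synonymous mutations subclonal.
TMB = non-synonymous mutations per targeted megabase. MSIsensor scores < 10
are MSS and > 10 MSI-high; a score of exactly 10 falls in neither published
band and is reported `indeterminate` rather than silently binned.

## Hotspot statistics

Substitutions are tested per residue. For a gene with n substitutions over L
residues and mutability weights w_i (uniform by default; a per-residue weight
column accepts trinucleotide-context-derived weights), the count at residue i
is Binomial(n, p_i) with p_i = w_i/Σw. The reported p-value is the upper tail
P(X ≥ k); by default it is *truncated* — conditioned on the residue being
mutated at all, P(X ≥ k)/P(X ≥ 1) — because only mutated residues are ever
tested; the unconditioned tail is available via a toggle. Only positions with
k ≥ 1 enter the testing family (k = 0 has p = 1 by construction and the
truncated model conditions on ≥1 event).

In-frame indels are grouped by overlap into single-linkage clusters; each
cluster's region is the intersection of its members, falling back to the
first maximal run of positions with the deepest overlap when a chain has an
empty global intersection. Regions are tested with the same binomial tail at
uniform background p = span/L, with n the gene's indel count (no mutability
model).

All residue and region p-values are pooled into **one** family and adjusted
with Benjamini–Yekutieli (step-up with harmonic-number inflation, valid under
arbitrary dependence); q < 0.1 is significant. The family structure is a
package choice — per-gene families would change q-values but not the control
guarantee. Calibration is checked empirically: on 20 replicates of a
220-gene cohort (200 null genes, 20 with planted hotspots) the observed FDR
among calls is far below the 0.1 operating point, with >95% sensitivity for
20-of-50 recurrent-mutation hotspots on a 500-residue protein.

## Duplex consensus and plasma calling

Reads sharing a canonicalised key (lexicographically sorted UMI tag pair +
fragment start/end, 1-based inclusive) form a family. Per strand, a simplex
consensus base requires ≥90% agreement (configurable) and ≥1 read (the
assay's minimum family size per strand is not publicly fixed; 1 is the
default and is configurable); the duplex base requires both strand
consensuses present and equal, else N; single-strand families emit nothing.
Raw errors at rate e per base therefore survive only when both strands err
identically, entering the duplex pileup at ~e² — the simulated pileups use
exactly that residual.

Calling filters: duplex AF ≥ 0.1% (limit of detection), duplex alt reads ≥1
at known cancer hotspots / ≥3 elsewhere, and removal of any variant with ≥1
alt duplex read in the matched buffy coat ("observed" is taken literally; the
threshold is configurable). A variant at zero duplex depth is reported
not-assessable, never absent.

Fragment-size discrimination is a one-sided Mann–Whitney rank-sum test for
candidate fragments shorter than the germline/WBC reference (≥10 fragments
per group), with the median difference as the shift estimate. Fusion allele
fraction = spanning support / mean of the two flanking depths, clipped to 1
with a warning. Phasing counts fragments covering both positions of a pair:
cis when both-alt / informative ≥ 0.8, trans when ≤ 0.2, ambiguous between,
not assessable below 3 informative fragments — deliberately conservative
bounds, since published read evidence for cis compound alleles is essentially
all-or-none.

## Trajectories and subclone grouping

Shedding at baseline: `shedding` when the enrolling alteration passes (or
other somatic calls pass at appreciable levels), `minimal` when the enrolling
alteration is absent but 1–3 other calls pass at AF ≤ 0.8% (a heuristic cap
taken from the observed range in discordant samples, not an assay rule),
`none` when nothing passes. Percent reduction = 100·(af₀ − af_t)/af₀.
Emergent = not passed at baseline, passed later.

Subclone grouping formalises the qualitative read of trajectory plots. A
variant is *quantifiable* at a timepoint when it passed or its AF ≥ LOD;
below-LOD points count as AF 0 for change signs. Per-interval signs use a
dead band: |Δaf| < 0.1 × the variant's first quantifiable AF counts as zero
(knob exposed) to stop noise-driven splits. The driver seeds subclone 1 and a
variant joins it when all intervals where both are quantifiable have agreeing
signs (zero agrees with anything); a variant sharing *no* quantifiable
interval with the driver is only eligible if it was quantifiable at baseline
alongside it — otherwise late-emerging variants would join the driver clone
vacuously once the driver falls below detection. Remaining variants group by
first-emergence timepoint plus pairwise sign concordance (connected
components). Envelopes are per-timepoint min/max over members' observed AFs.

## Mechanism classification

Rules are applied with set semantics (mechanisms co-occur): emergent RET
solvent-front/gatekeeper/roof allele → on-target secondary (a
gatekeeper + roof pair phased cis is additionally reported as a compound
allele, e.g. V804M/Y806C); emergent oncogenic RAS/BRAF allele → bypass
mutation; emergent amplification of MET/FGFR1 → bypass amplification;
baseline oncogenic RAS allele rising while the driver falls → primary RAS;
otherwise none identified. Polyclonal when ≥2 mechanism-bearing variants sit
in distinct subclones; evidence without a subclone assignment is flagged
unphased. Amplifications are boolean inputs (focal amp present), matching how
studies report them. The knowledge table is a versioned, editable TSV bundled
with the package; nothing is fetched from a network service.

Detection rates and the clinical benefit rate are reported to the next whole
percent (ceiling), which reproduces the conventional presentation of
18/19 → 95% and 36/49 → 74%; clinical benefit = SD/PR/CR lasting ≥24 weeks or
ongoing.

## Synthetic cohorts

The generator emulates: a truncal clone (tissue CCF 1) plus subclones;
Poisson depths around configured means (tissue 500×, plasma duplex 1200×,
matching reported panel and duplex coverage scales) with binomial alt counts
(a beta-binomial overdispersion knob exists, default off); per-clone plasma
AFs following single exponentials af₀·e^{rt} clipped to [0,1], with an
optional piecewise rate switch at a progression day to emulate emergent
resistant clones (the true shedding kinetics of patients are unknown — the
exponential is an explicit stand-in, chosen as the minimal model reproducing
published response/progression shapes); duplex read families with per-read
errors; CH contaminants at constant AF with fragment lengths ~N(167, 20) vs
tumor ~N(145, 20), truncated to [50, 400] bp, consistent with published cfDNA
biology; and a quadratic residual error in duplex pileups (see above).
Everything derives from one integer seed; identical seeds give byte-identical
outputs.

Default study conditions used in validation (chosen once, as realistic for
this setting): baseline driver AF 4% responding at −0.05/day; emergent clones
start at AF 10⁻⁴ and grow at +0.2/day from staggered progression days so each
becomes detectable at a distinct 28-day follow-up draw; tracking cohorts use
100 patients with 2–4 clones × 5 variants at duplex depth 2000; CCF
validation uses 500 variants at depth 1000 (error) and 1000 at depth 200
(coverage) at purity 0.6.

What passing does *not* show about real data: no alignment or raw-calling
artifacts, no mutational-signature realism, no inter-patient purity/CN
variation beyond configuration, binomial (not overdispersed) counts by
default, and clean exponential dynamics — real trajectories mix kinetics,
sampling irregularity and assay batch effects the generator does not model.

## Numerical notes and limitations

* CCF grid step 0.01 bounds point-estimate precision; ties in the posterior
  argmax resolve to the smaller grid value via `argmax`.
* Multiplicity rounding at exactly x.5 follows Python banker's rounding; in
  practice unreachable except at contrived MAFs.
* `group_indels_mcr` is single-linkage: one long indel can chain otherwise
  separate clusters; the maximal-depth fallback then picks the first deepest
  run (ties broken leftward).
* Subclone grouping assumes clones differ in emergence time or trajectory
  direction; two clones responding at similar rates from baseline are not
  separable from plasma dynamics alone and will merge.
* The mechanism classifier trusts its annotations; alleles missing from the
  knowledge table are untagged and can only contribute none-identified.
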