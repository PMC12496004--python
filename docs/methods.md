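# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not establish.

## Cohort table and grouping

The packaged per-sample table covers 64 neoplastic specimens of 33 germline
MMR-variant carriers. Histology codes map deterministically to analysis
groups: EEC, CCEC and CxEC form the endometrial-carcinoma (EC) group — the
cervical adenocarcinomas are deliberately grouped with EC, which is what
makes the EC group count 27 and is confirmed by the EC mean-TMB
reconstruction — EOC and CCOC form the ovarian (OC) group, and CAH forms
the atypical-hyperplasia (AH) group. Timepoints are years relative to the
carcinoma endpoint (0 = endpoint, negative = earlier), so they are never
positive. VAFs are stored as fractions in [0,1]; percent values are
converted at IO boundaries and displayed rounded half-up to whole percent.
Mean burdens and variant counts are displayed rounded half-up to one
decimal; p-values to three decimals with "< .001" below 0.0005. Missing
MSI/IHC measurements stay missing — a sample with neither has undefined MMR
status.

## Filtering

A somatic variant is significant when the caller's somatic p-value is
< .01, VAF ≥ 5%, caller status is PASS, and the effect is non-synonymous.
The VAF boundary is inclusive (≥): the per-sample table treats a 5% VAF as
passing, and the strict alternative is available as a policy flag. Manual
read-level curation cannot be automated, so it is consumed as a decision
table (kept / quality / misplaced reads / misinterpretation / blood VAF);
variants with blood VAF > 5% are additionally removed to avoid confusing
tumor variants with clonal hematopoiesis. Low-level probing of normal
tissue calls a variant present at ≥ 5 supporting reads and ≥ 1% VAF; zero
coverage is a distinct verdict, never "absent".

## Burden

TMB = significant non-synonymous variants / panel megabases (6.4 Mb
default). The hypermutation boundary is TMB ≥ 10/Mb: the source series
flags a sample at exactly 10.0/Mb as hypermutated while describing the rule
in prose as "over 10", and the inclusive reading is the one consistent with
every per-sample flag (verified 64/64 in the tests). TMB is kept at full
precision internally and rounded only for display.

## MMR engine

MSI: at least one marker deviating by ≥ 2 nt. MMR deficiency: MSI or IHC
protein loss or both; proficiency requires all evaluable evidence negative.

LOH at the constitutionally heterozygous pathogenic site uses the ratio
(alt:ref)ᵀ/(alt:ref)ᴺ. The strict/putative thresholds (2.0 and 1.5, with
reciprocals for loss of the mutant allele) are inherited from the
conventional two-fold allelic-imbalance criterion of the cited
methodology; they are configurable. When any read count is zero a 0.5
pseudocount is added to all four counts (Haldane-style), keeping the ratio
finite and symmetric; a homozygous normal is "not informative". Only loss
of the wild-type allele counts as a second hit; mutant-allele loss is
recorded but never reported as one. At modest depth the putative band has a
non-trivial false-positive rate on balanced sites (the log-ratio standard
deviation at depth 100 is ≈ 0.3), so putative calls should be read together
with the ratio value.

Second hits per sample combine wild-type LOH/pLOH and somatic variants of
the predisposing gene. The rescue rule: a variant below the 5% cut-off is
still attached to a sample — flagged sub-threshold, exact VAF kept — when
the identical variant reaches 5% in another sample of the same patient.
Cohort-level summary counts ("any second hit") use the strict definition
(wild-type LOH/pLOH or a ≥ 5% variant); rescue affects only per-sample
reporting and trajectory display. This distinction is what reproduces the
16/22 AH second-hit count and the [[16,4],[0,2]] exact-test table.

## Sharing and trajectories

Variant identity is the normalized (chrom, pos, ref, alt): shared suffix
bases are trimmed, then shared prefix bases (advancing pos), and with a
reference sequence indels are left-aligned through repeat tracts, so caller
representation differences cannot break identity. Sharing percentage =
shared/(shared + unique₁ + unique₂); directional fractions divide by each
lesion's own total. Asymmetric comparisons (different policies per side)
are rejected; a zero-variant pair returns 0 with a degenerate flag.

Trajectories list a variant when it is called in a carcinoma and (for
configured histology-specific driver genes) at least one hyperplasia, or
(for other panel genes) at least two hyperplasias. Second-hit variants of
the predisposing gene are always traced and their rule satisfaction is
flagged separately — the display convention ambiguity is resolved in favor
of never hiding the second hit. Driver-gene lists are versioned external
content and ship as explicit configuration (empty by default, with a loud
warning). VAF display bins (<5%, 5–15%, 15–30%, >30%) are a reporting
convention of this package; exact VAFs accompany sub-5% and probed
normal-tissue values.

## Clonal-relatedness test

The external clonality software used by the emulated analysis names only a
"likelihood test"; this package defines its own explicit instantiation and
validates it by simulation rather than by matching external internals.

Given reference marginal mutation probabilities p_j (estimated with a
pseudocount: p_j = (hits_j + c)/(n + 2c), c = 0.5 by default), the null
holds the two binary gene-level profiles independent Bernoulli(p_j). The
alternative mixes in clonality: with probability ξ a gene behaves clonally
(both tumors share one Bernoulli(p_j) outcome), otherwise independently:

    P(1,1) = ξ p_j + (1−ξ) p_j²        P(1,0) = P(0,1) = (1−ξ) p_j (1−p_j)
    P(0,0) = ξ (1−p_j) + (1−ξ)(1−p_j)²

Marginals are preserved, and the parametrization is symmetric in the two
tumors. The likelihood is evaluated over genes mutated in at least one
tumor of the pair: on a mostly-unmutated panel, concordant absence is not
treated as evidence of shared origin, so disjoint profiles give ξ̂ = 0 and
statistic 0 identically. Each per-gene term is linear in ξ, hence the
log-likelihood is concave; it is maximized by golden-section search on
[0,1] (40 iterations, interval < 1e-8, verified against a 1e-4 grid to
1e-6). The statistic is 2(max ℓ − ℓ(0)), clipped at 0.

Significance is Monte Carlo: null profiles are drawn as independent
Bernoulli(p_j) conditioned on each tumor's observed mutation count — exact
conditional-Bernoulli sampling through the elementary-symmetric-polynomial
recursion in log space — which keeps mutation burden from masquerading as
relatedness. p = (1 + #{simulated ≥ observed})/(1 + n_sim), never zero.
Calibration (fixed seeds, documented in the tests): type-I error at α=.05
over 500 independent pairs on a 40-gene reference with marginals 0.02–0.25
lies within the binomial confidence band of .05 (the conditional
construction can only be conservative); power on pairs with true ξ = 0.8
over a 200-gene rare panel (marginals 0.01–0.10, ≈ 9 mutations per tumor)
exceeds 0.8. A practical caveat demonstrated in `analysis/04`: on a small
panel, hypermutated lesions saturate every gene and gene-level profiles
carry no clonality signal — the test then correctly returns p ≈ 1 rather
than a spurious verdict.

## Microsatellite scanner

A microsatellite is a maximal tandem repetition of a primitive 1–5 bp unit
with ≥ 3 complete units and ≥ 5 bases. Trailing partial units extend the
reported region (standard repeat-finder behavior); whether the partial
bases count toward the length minimum is configurable (default: they do).
Units are canonicalized to the smallest period; overlapping candidate
regions are resolved by priority (longer region, then smaller unit, then
leftmost). Non-ACGT characters never extend a repeat. Output is 0-based
half-open (BED); the scanner is checked against an independent regex
enumeration oracle on 1,000 random sequences and for reverse-complement
invariance. A variant hits a repeat when its affected interval (reference
span for substitutions and deletions, anchor plus junction base for
insertions) intersects a region.

## Statistics

Fisher's exact test (two-sided, minimum-likelihood rule — the sum of
hypergeometric probabilities not exceeding the observed table's) is
delegated to scipy and verified against full margin enumeration for all
tables with n ≤ 40; degenerate margins return p = 1 with a flag.
Mann–Whitney U uses the asymptotic two-sided form with tie/continuity
corrections; Kruskal–Wallis is followed by Dunn's pairwise z-tests on
pooled mean ranks with tie correction and optional Bonferroni adjustment
(written here directly, as no post-hoc library is a dependency).

## Synthetic-cohort generator

The generator's defaults are the emulated study conditions: 33 patients
(MSH2 fraction 5/33, otherwise MLH1), one endometrioid carcinoma per
patient with an atypical hyperplasia in 21/33 (preceding the carcinoma by
1–9 years in 6/22 of those), a synchronous second carcinoma in 9/33, blood
available in 24/33 (otherwise a normal-endometrium reference); hypermutator
probability 0.8 with rates 40 vs 2 variants/Mb on a 6.4 Mb panel; truncal
fraction ξ = 0.26 (the observed mean directional sharing between
hyperplasia and carcinoma); LOH second-hit probability 0.3; tumor purity
0.7; mean depth 200 (negative binomial, dispersion 10); frameshift fraction
0.35 with repeat-placement bias 0.7.

Each patient draws a truncal variant set (Poisson, ξ × rate × panel) shared
by every lesion plus per-lesion private sets (Poisson, (1−ξ) × rate ×
panel), so a lesion's expected total is rate × panel and the *directional*
sharing fraction of a pair estimates ξ directly (the symmetric percentage
converges to ξ/(2−ξ)). True VAF is clone fraction × purity / 2 (truncal
clones at fraction 1, private 0.5–1), observed through binomial sampling at
the drawn depth. The second hit is per lesion: LOH shifts the
pathogenic-allele fraction at the germline site to 1/(2−purity), a variant
mechanism plants a clonal nonsense variant in the predisposing gene —
passenger variants are placed only in non-MMR panel genes so the simulated
mechanism stays unambiguous. Gene sequences are synthetic 2 kb contigs with
planted mononucleotide tracts; the authoritative repeat map is what the
scanner finds on the finished sequence. Patients use spawned seed
substreams, so a cohort can grow without perturbing existing patients.

What the generator does **not** emulate: subclonal structure (one dominant
clone per lesion), copy-number landscapes beyond the single LOH site,
sequence-context mutational signatures, sample contamination and FFPE
artifacts, and caller-specific error modes (somatic p-values of true
variants are drawn uniformly below the threshold). Passing recovery tests
therefore demonstrates the pipeline's correctness under its own model
assumptions, not robustness to every artifact of real panel data.

## Problem sizes in the validation suite

The default suite runs the scanner oracle on 1,000 sequences (lengths
10–400 with every hundredth at 2,000), the exact-test enumeration on 400
random tables, clonality calibration on 500 null pairs and 200 clonal pairs
at n_sim = 999, and recovery simulations of 30–40 patients at depths
100–200 — sizes chosen so the statistical assertions have the power quoted
above while the whole suite stays fast to run routinely.

## Known limitations

- Cohort-level "any second hit" counts recomputed from the per-sample table
  differ by one from some published group totals (23 vs 22 EC samples; 18
  vs 17 LOH/pLOH samples overall), traceable to an informativeness
  denominator that the per-sample table does not encode; both counts are
  reported and the exact-test conclusions are unaffected.
- Reference mutation frequencies for the clonality test must be supplied or
  estimated from the cohort itself; external reference series are not
  bundled.
- The microsatellite scanner is exact-repeat only; mismatch-tolerant
  repeats are out of scope.
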