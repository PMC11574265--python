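# Methods

## Scope and model

`codonopt` quantifies how well coding sequences are matched to a measured
tRNA pool, and how codon content relates to decoding speed and mRNA
stability, in five connected stages:

1. **CDS validation and codon tabulation.** A coding sequence is accepted
   when it starts with ATG, ends with a stop codon (TAA/TAG/TGA), has length
   divisible by three, contains no ambiguous bases, and no premature stop.
   Rejection reports only the first failure in that fixed order, so verdicts
   are deterministic. Per-transcript codon statistics exclude the start ATG
   and the terminal stop by default: the initiating methionine is delivered
   by the initiator tRNA and should not be pooled with elongation events.
   Internal ATGs count as Met.

2. **Wobble-aware codon→anticodon assignment.** Each of the 61 sense codons
   is assigned to exactly one anticodon family. A codon that is the reverse
   complement of a family's anticodon is a Watson-Crick assignment. Two
   wobble duplication rules cover the rest: a G34 family also reads the
   U-ending synonym of its C-ending codon, and an A34 family (inosine at
   position 34 in the mature tRNA) also reads the C-ending synonym of its
   U-ending codon. No superwobble (U34 reading four codons) and no
   I34→A-ending triplication are modelled; the two pairwise rules are the
   ones with clear support across eukaryotic cytosolic repertoires, and
   they make every wobble relationship a *pair* of synonymous codons. With
   the default repertoire this yields 16 wobble pairs (8 from the eight
   inosine families). No selective wobble-efficiency penalties are applied;
   a wobble-decoded codon inherits its family's full abundance.

3. **Adaptation indices.** CAI weights are pooled codon counts over a
   reference set of the most highly expressed transcripts
   (ceiling(top_fraction·N) by mean TPM, default top 5%, ties broken by
   transcript id), each weight scaled to the most frequent synonymous codon;
   absent codons receive a 0.5 pseudo-occurrence (Sharp–Li convention).
   etAI weights are the measured per-family read proportions mapped through
   the decoding rules, deliberately *not* rescaled to the maximum weight —
   the most abundant family can differ between conditions, and rescaling
   would erase exactly that signal. As a consequence etAI scales linearly
   with the profile and is not bounded by 1. Per-transcript scores are
   geometric means of per-codon values over counted codons, computed in log
   domain (the direct product underflows IEEE doubles beyond a few hundred
   codons). Decoding rates are 1/DT from a relative dwell-time table.

4. **Half-lives.** First-order decay is fit as a linear regression of
   log2(TPM) on time with the slope bounded above by 0 (for a simple line
   the bounded least-squares solution is min(OLS slope, 0)). Then
   k = −slope·ln2 and t½ = ln2/k. Transcripts are filtered, in order, for
   low starting expression (TPM at t=0 ≤ 10 by default), a non-decreasing
   trend (bounded slope exactly 0), and a poor fit (slope p-value ≥ α from
   the *unconstrained* regression; for a simple regression the slope t-test
   and the model F-test coincide). Zero TPM values truncate the course at
   the first zero because log2 is undefined there; a course with fewer than
   three positive points is an error, not a silent filter.

5. **Codon stabilization coefficients.** The CSC of a codon is the Pearson
   correlation across retained transcripts between the codon's occurrence
   and the transcript half-life. Occurrence defaults to per-transcript
   frequency (count / counted codons), which removes CDS-length
   confounding; a raw-count mode is exposed for sensitivity analysis.
   Significantly positive codons (p < 0.05) are stabilizing, significantly
   negative destabilizing, the rest neutral. The threshold is unadjusted by
   default, matching the common CSC convention; a Benjamini–Hochberg option
   exists (`adjust=True`). Zero-variance codons get an undefined CSC and
   class neutral.

## Statistical primitives

* **Fisher z comparison** of two correlations uses the independent-samples
  form z = (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3)) with a two-sided
  normal p. The correlations compared here come from different stages with
  different transcript populations, so the dependent-overlapping variant is
  out of scope.
* **Rank tests** (Mann–Whitney U / Wilcoxon rank-sum; same test, different
  statistic convention) enumerate the exact null over all C(n1+n2, n1)
  group assignments when n1+n2 ≤ 12 (two-sided p = 2·min(tails), capped at
  1, midranks for ties) and otherwise use the normal approximation with tie
  correction and 0.5 continuity correction.
* **Misincorporation comparison** builds a 2×2 table (misincorporated vs
  read-through per condition), reports the natural-log odds ratio with the
  Haldane–Anscombe 0.5 correction on zero cells, a Yates-corrected
  chi-square p, and BH q-values; sites are significant at q ≤ 0.01.

## The default anticodon repertoire

The zebrafish cytosolic pool comprises 47 anticodon families. The built-in
table lists the standard eukaryotic set: 45 elongator families plus
initiator Met-CAT and Sec-TCA. Initiator Met and Sec are carried in the
repertoire (they are part of measured profiles) but never decode sense
codons; elongator Met-CAT reads ATG, and Sec-TCA's UGA readthrough is
excluded. The repertoire is data, not code: a TSV with columns
`amino_acid`, `anticodon`, `class` overrides it, and the decoding map is
rebuilt from whatever repertoire is supplied, erroring with the list of
uncovered codons if the rules cannot cover all 61.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical *structure* the analysis assumes,
with analytic ground truth:

* anticodon proportions are symmetric Dirichlet draws (default
  concentration 2 over 47 families, giving the skewed-but-complete pools
  seen in real tRNA-seq);
* dwell times follow dt ∝ supply^(−β) with lognormal noise (defaults β = 1,
  σ = 0.3), normalized to geometric mean 1, so log dwell time is
  anti-correlated with log supply by construction;
* CDS sets are ATG + sampled sense codons + stop, with per-transcript codon
  distributions drawn from a Dirichlet around a common bias (total
  concentration 150, lengths 100–400 codons by default). The heterogeneity
  matters: between-transcript compositional variance is what makes a CSC
  estimable at all, and the chosen concentration gives a spread comparable
  to across-gene codon-usage variation in real transcriptomes;
* decay is additive in codon content, k = k0 + Σ_c w_c·freq_c (k0 = 0.2/h),
  with lognormal measurement noise (σ = 0.1) on TPM over a 0–8 h hourly
  grid and lognormal initial abundances (median 300 TPM). The additive
  parameterization keeps the sign and ranking of per-codon effects
  analytic. `decay_weights_from_supply` derives graded weights
  λ·0.1·(−log supply), coupling slow decoding to fast decay; raising λ
  strictly increases the correlation between transcript etAI and fitted
  half-life — the synthetic analogue of translation-driven sensitization of
  decay to tRNA supply.

Passing recovery tests on these inputs shows the estimators are correct
under the model's own assumptions. It does not show robustness to what the
generator omits: secondary-structure or UTR-motif effects on stability,
poly(A)-tail dynamics, positional codon effects, sequencing-depth noise,
isoform mixtures, or miscalibrated TPM normalization.

## Numerical choices and problem sizes

Geometric means are log-domain; proportions are validated to 1e−9; exact
rank-test enumeration switches to the asymptotic form above a pooled size
of 12 (924 assignments enumerated at the boundary). The recovery suites
use 500 transcripts for classification-style checks and 2000 for rank
recovery of graded codon weights (CSC sampling noise scales as 1/√n and
dominates rank agreement at small n), 1000 transcripts for the noisy
half-life error distribution, and 2000 replicates at n = 100 for the
Fisher z type-I calibration. All generators are deterministic given a seed.

## Known limitations

* The decoding rules are purely structural; organism-specific wobble
  efficiencies are not modelled (by design).
* CAI weight pooling uses counts, not per-gene frequencies; for pooled
  counts the two differ only by length weighting within the reference.
* The half-life fit assumes a single exponential; biphasic decay is
  reported as whatever single slope fits best, flagged only through the
  fit p-value.
* `fit_half_life` applies the low-expression filter to the first tabulated
  time point, which is assumed to be t = 0.
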