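# Methods

This note records the models the package implements, the defaults it
ships, and what its synthetic benchmarks do and do not demonstrate.

## Cleavage-site calling

A fragment observed by LC-MS/MS and assigned to a parent library peptide
implies hydrolysis of the bonds at its termini: a fragment spanning parent
residues *s..e* (1-based) implies bond *s−1* (unless it starts at the
N-terminus) and bond *e* (unless it ends at the C-terminus); the intact
peptide implies nothing. Bonds are indexed 1-based, bond *b* joining
residues *b* and *b+1*. Fragments matching at several parent offsets are
accepted only when every placement implies the same bonds; otherwise they
are an error — a search engine cannot localise them either. An optional
mapping treats fragment leucine as matching library norleucine, because
norleucine (the Met replacement used in synthesis) is reported as Leu by
search engines.

Reporting follows the assay's two filters:

* **Replicate intersection** — a site counts for an enzyme at a timepoint
  only if inferred in *every* biological replicate at that timepoint
  (≥ 2 replicates required; the rule is undefined otherwise).
* **NEC subtraction** — any site seen in any no-enzyme-control replicate
  at any timepoint is blacklisted. Using a single global blacklist makes
  the order of intersection and subtraction irrelevant:
  `(∩_r S_r) \ B = ∩_r (S_r \ B)` for any fixed B.

Accumulative sets are prefix unions over the sorted schedule (default
60/120/240/480 min), hence nested by construction; overlap statistics
between enzymes are defined on accumulative sets at a common timepoint.
Spectral counts are carried through but never used for calling, which is
presence/absence.

## Positional enrichment statistics

Windows are the eight residues P4..P4′ around a bond, padded with `-`
beyond the peptide termini; pads are excluded from all counts, so
per-position observation counts differ (for a 14-mer library, P4 loses
the first three bonds of each peptide). Frequencies are counts with
multiplicity — duplicated windows are *not* deduplicated, because the
reference should reflect the sampling odds of a random cleavage among the
bonds actually offered. The background is the all-sites window set of the
same library, not a proteome.

The per-cell statistic is the binomial-approximation Z-score
`(f_exp − f_ref)/sqrt(f_ref(1−f_ref)/n_exp)` with the positive set's
per-position n — the iceLogo formulation — and a two-sided normal
p-value at α = 0.05 by default, uncorrected across the 8×20 cells to
match raw-p logo shading (a Benjamini–Hochberg switch exists). Cells with
f_ref ∈ {0, 1} have no defined Z and are flagged rather than dropped.
Against an exact binomial oracle the normal approximation reproduces the
significance call on ≈ 98–99% of realistic random cells (n ≤ 500);
disagreements sit at the decision boundary.

The difference map is `z_A − z_B` with both enzymes profiled against the
*same* background (enforced), which makes it exactly antisymmetric. The
alternative — a direct two-sample statistic per cell — would weight the
two sets' sizes differently; the differenced form matches how per-enzyme
profiles are produced and compared in practice.

Ratio outputs (fold changes, tetrapeptide log2 ratios, C-terminal
enrichments) floor zero frequencies at a pseudo-frequency of
`1/(2·n_obs)`; the floor is never applied to Z-scores or raw scores.

## Tetrapeptide ranking and MHC cleavage scores

Both use the same product-of-positional-frequencies form. A tetrapeptide's
score under a matrix is `f(P4,a4)·f(P3,a3)·f(P2,a2)·f(P1,a1)`; all
`20^4 = 160,000` sequences are scored and sorted by log2 ratio with a
lexicographic tie-break. An MHC I peptide's score aligns the same product
to its C-terminus (P1 = final residue), using the *positive-set*
frequencies rather than background-normalised enrichments — the score
asks how often the enzyme was observed to cut in that local context, not
how surprising the context is; an enrichment-weighted variant is a flag
away. No positional weighting is applied: nothing in the assay calibrates
relative subsite importance. Scores are invariant to peptide content
N-terminal of P4. Methionine (absent from the norleucine-substituted
library alphabet) is mapped to norleucine by default, or rejected.

Assay peptides concatenate the MHC peptide's last seven residues with the
first seven residues of downstream parent-protein context, putting the
processing site at bond 7 of a 14-mer. Balanced selection bins candidates
by log2-ratio quantiles (five bins by default; duplicate quantile edges
collapse, so few distinct scores give fewer bins and identical scores
reduce to a simple random sample) and draws equally per bin, spreading any
remainder deterministically from the most populous bins; draws are
reproducible under a seed.

## Kinetics

Initial rates come from a least-squares line forced through the origin —
no product exists at t = 0 — over the curve's linear region: the longest
prefix of timepoints with areas at or below 50% of the curve maximum,
extended to at least three observed points. A curve at plateau from its
first point has no linear region and reports rate 0 (flagged); all-zero
curves likewise. On a saturating curve `A(1−e^(−kt))` sampled at the
default 15–2880 min schedule this recovers the true initial slope `A·k`
to within ~10%, the truncation bias of any fixed linear-region rule. Both
cutoff and minimum points are configurable.

Selectivity averages a substrate's two product rates within each
replicate, then across replicates: `log2(mean v_A / mean v_B)`. The
p-value is a two-tailed equal-variance Student t-test on log2-scale
per-replicate rates (log transformation stabilises the multiplicative
noise; the classical equal-variance form matches the named test). Zero
rates are floored at half the substrate's smallest positive rate for the
log only, flagged; substrates quantified in one enzyme only are flagged
infinite-selectivity and excluded from testing. An optional per-enzyme
scalar represents activity normalisation of the enzyme preparations.
The statistic is invariant to rescaling all areas.

Multiple testing uses Storey's estimator with
`π̂0 = min(1, #{p > λ}/((1−λ)m))` and monotone step-up q-values; at the
default λ = 0, π̂0 = 1 and the q-values equal Benjamini–Hochberg adjusted
p-values exactly (verified against an independent implementation).
Significance is q < 0.05.

## Synthetic-data generator

The generator exists to give every stage a ground truth. Digestion is a
first-order competing-risks model: bond *b* carries hazard
`k_b = k0 · Π_j w(j, residue_j)` over its window (pads contribute 1), and
with `K = Σ k_b` the probability bond *b* is the peptide's first cut by
time *t* is `(k_b/K)(1 − e^(−Kt))`, which conserves probability exactly.
Products are not re-cleaved: the assay operates at low conversion and
early timepoints where secondary cleavage is rare. Detection is a
threshold on expected conversion plus Bernoulli dropout per reported
fragment — deliberately not an ionisation model, but enough to exercise
the replicate and NEC filters. Products shorter than 4 residues or with
ambiguous placement are not reported, mirroring what a search engine can
identify; every bond of a 14-mer retains at least one 7-residue product.
NEC samples contain a Poisson number of spurious sites per replicate.

Truth presets are directional caricatures of the two proteasome isoforms:
the iP-like preset elevates Trp/Phe/Tyr/Leu at P1 (8/6/5/3 before
normalisation), the cP-like preset elevates Ser/Thr/Gln/Arg/Gly/Ala
(6/5/4.5/3/2.5/2.5), and both elevate Lys at P2 (3). Weights are
normalised to geometric mean 1 per position, which preserves all ratios.
Because the presets exaggerate divergence (only the P2 lysine is shared),
the two enzymes' called sets overlap far less on synthetic data than real
proteasome profiles do — the generator demonstrates recoverability of
differences, not the realistic degree of overlap.

Defaults define the simulated study conditions: 228 peptides × 14
residues; 2 replicates; timepoints 60/120/240/480 min; `k0 = 6.3e-6
min⁻¹`, calibrated by bisection so the median peptide-level conversion at
480 min is 5% (per-bond conversion saturates at the hazard share `k_b/K`
and is not a free target); detection threshold 0.0075 conversion, which
puts the called fraction at ~14–15% of library bonds for both presets —
the low-conversion regime the assay operates in; dropout 5%; five
expected NEC sites per replicate; lognormal noise CV 10%; four replicates
and the 15–2880 min schedule for progress curves. Proteomes and
MHC-peptide pools are i.i.d. draws from a configurable composition
(uniform by default) — no codon bias, domain structure, or binding-motif
structure, so composition comparisons on synthetic data only test the
arithmetic, not biological effect sizes.

What passing synthetic benchmarks shows: the pipeline recovers a planted
P1 preference ordering (Pearson r ≥ 0.9, top-3 exact for ≥ 4× effects)
and planted rate ratios over |log2| ≤ 4 (median error ≤ 0.3 at CV 10%,
n = 4) under this noise model. What it does not show: robustness to
ionisation bias, chimeric identifications, retention-time effects, or
real replicate correlation structure, none of which are modelled.

## Numerical and degenerate-input choices

Frequencies sum to 1 per position to 1e-9; all-pad positions are errors.
Ambiguous fragments and unknown parents are hard errors, never silently
dropped. Identical rate vectors give p = 1 (NaN from a zero-variance
t-test is mapped to 1: no evidence of difference). Tie-breaks are
deterministic everywhere (lexicographic sequences, stable sorts, seeded
RNG streams derived from a single integer). The q-value step-up uses a
cumulative minimum from the largest p, capped at 1.

## Known limitations

* Calling is presence/absence; spectral counts are not modelled
  statistically.
* Specificity is per-position; subsite coupling (higher-order motifs) is
  out of scope.
* The MHC score uses non-prime frequencies only, so prime-side effects on
  processing are invisible to it (the rate assay sees them).
* The linear-region rule is a fixed heuristic; curves with very fast
  saturation between the first two timepoints will be underestimated.
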