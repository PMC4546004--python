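# Methods

This note records the models, estimators, conventions and numerical choices
behind the package, and what the synthetic-data tests do and do not
establish about real data.

## Haplotype processing

Sequences are upper-case IUPAC strings over {A, C, G, T, N, −}. Fragment
trimming removes fixed 5′/3′ primer stretches and, optionally, excises a
single homopolymer run: the maximal run of ≥ *k* copies of a base starting
inside a 0-based half-open window on the trimmed sequence, removed in full
even where it extends past the window edge. When no qualifying run exists
the sequence is returned unmodified with a warning — the rule, not a target
length, is the contract, so variable-length runs produce variable trimmed
lengths and the realised length is recorded.

Collapsing treats the gap character as a fifth state for identity (two
sequences differing only by a gap are different haplotypes) but excludes
gapped and N positions from all distance computations. A record containing
N joins an existing haplotype only when compatible with exactly one fully
resolved class; otherwise it is excluded and logged, which sacrifices a few
scat-derived records rather than guessing their membership. Haplotype names
for two-fragment data follow the letter–numeral convention (coding-fragment
letter before the dash, control-region numeral after), assigned in
first-observation order, so a concatenated table can be projected to either
single-fragment level by merging columns that share the relevant token;
projection conserves counts exactly.

## Diversity and divergence

Haplotype diversity is Nei's unbiased estimator with Nei's variance:

    h = n/(n−1) (1 − Σp²)
    V(h) = 2/(n(n−1)) { 2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)² }

Nucleotide diversity is the mean proportion of differing sites over all
C(n, 2) individual pairs, with pairwise deletion of ambiguous positions and
the Nei–Tajima total variance

    V(π) = (n+1)/(3(n−1)L) π + 2(n²+n+3)/(9n(n−1)) π².

Net divergence is d_A = d_XY − (π_X + π_Y)/2 with d_XY the mean distance
over all cross-group pairs. Within-group π here uses the same C(n, 2)
convention as the desktop tools. Consequence worth knowing: splitting one
panmictic sample into random halves gives E[d_A] = 0 exactly (the unbiased
behaviour the estimator is meant to have), whereas computing d_A of a group
against itself gives a small negative offset of order π/n — the two
properties cannot both be exact at finite n, and the unbiased-split one was
chosen. K2P-corrected distances are available per pair; p-distance is the
default as the primary reporting scale.

## Composite-rate dating

A rate model is a list of (fragment, length, per-site rate in percent per
million generations). The composite per-site rate is the length-weighted
mean; the per-sequence per-generation rate is composite × total length ×
10⁻⁸ (the two factors of 10⁻² and 10⁻⁶ from percent and per-million). The
standard models are 363 bp at 2.8 + 422 bp at 17.75 (composite 10.84,
printing as 10.8 %/Mgen, i.e. 8.5069 × 10⁻⁵ ≈ 8.51 × 10⁻⁵ per sequence per
generation) and, for whole mitogenomes, 15,478 bp coding at 2.8 + 982 bp
control region at 17.75 (3.69 → 3.7 %/Mgen). Rates are inputs, not
estimated from data.

rho converts to time as T = ρ/μ generations; the SD scales identically;
years multiply by the generation time (default 2.0 years, with a 1-year
mode for comparison with older work). Divergence windows are
percent ÷ (percent-per-MY rate) × 10⁶ years. Reporting convention:
full-precision values are always retained; printed values round generations
to integers, divergence-window years to the nearest 1,000 and mitogenome
ages to the nearest 10,000, with halves away from zero (812,500 → 813,000).
Published TMRCA tables produced with a slightly different internal rounding
of the per-sequence rate differ from full-precision conversions by ≤ 0.05%;
one published row (ρ = 1.08 → 12,725) is inconsistent with every other row
under any single rate and is flagged rather than reproduced.

## Generation time from age classes

Under geometric adult survival s, expected counts in age classes 1, 2, …
fall as s^(x−1), so ln(count) is linear in class with slope ln s. The
default fit regresses ln(n_x/n_ref) on (x − x_ref) through the origin with
the first non-empty class as reference — the only reading of a
"zero-intercept" log-count regression that yields a survival rate — and
weights classes by their counts (var(ln n) ≈ 1/n for multinomial counts;
without weighting, the two- or three-animal oldest classes dominate the fit
through their leverage and the estimator misses the ±0.05 recovery band in
~18% of n = 435 draws, versus ~3% weighted). The literal unnormalised
zero-intercept fit is exposed for comparison; on unscaled counts it is
degenerate (it forces a count of one at age zero) and is reported without a
survival interpretation when exp(slope) ≥ 1. The fitted model's mean adult
age is 1/(1−s), also reported empirically from the table. Interior
zero-count classes are excluded with a warning by default, or kept with a
0.5 pseudo-count.

## Median-joining networks and rho

Distances are Hamming counts over unambiguous sites. The network starts
from the ε-relaxed minimum spanning network: an edge is feasible when its
distance is at most the connection level of its endpoints (the smallest
distance class at which they join) plus ε. Each feasible link, combined
with every third node, proposes quasi-medians — position-wise majority
vectors, expanding all choices where the three states are distinct (capped
at six fully tied positions) — and all new medians within ε of the minimal
connection cost are added; the cycle repeats to convergence. Obsolete
median vectors (unsampled, degree ≤ 2, removable without stretching any
sampled-to-sampled shortest connection) are then deleted. Median vectors
are named mv1, mv2, … in creation order with a content hash for
reproducibility. Character weighting is uniform and ε defaults to 0, the
published defaults.

Two deliberate conventions:

- A sampled-MSN link is retained unless the added medians supersede it with
  an equally short path. This keeps every sampled pair connected at its MSN
  distance without the cycles that blanket MSN retention would close
  through medians sitting on geodesics.
- The candidate-triplet rule (each link plus any third node) is the broad
  form: on random binary instances checked against an exhaustive
  Dreyfus–Wagner Steiner oracle the narrower both-pairs-linked rule missed
  the optimum noticeably more often. Even so, the ε = 0 search is greedy
  and misses the exhaustive Steiner length on a few percent of adversarial
  random instances; raising ε (the tool's documented escalation) recovers
  them. The relaxation trades sparseness for search breadth.

rho is the frequency-weighted mean shortest-path mutation count from an
ancestral node to each sampled individual (weights are individual counts,
not one per haplotype, which matches the magnitude of published SDs). The
variance follows Saillard's subtree-weight form computed on shortest-path
edge flows: σ² = Σ_edges (w_e/n)² × length_e, where w_e is the number of
individuals whose path crosses the edge; for a star of singletons this is
Σlᵢ/n². Where several co-shortest paths exist the individual's weight is
split equally among them — rho itself is unaffected (all co-shortest paths
share one length); only the SD is, and averaging removes order dependence.

Node polarity: tips are degree-1 sampled nodes, everything else is
interior; a root hint (outgroup sequences or a designated node) marks the
closest sampled node as root-proximal, ties broken by lowest name and all
reported.

## AMOVA, SAMOVA, Mantel

Molecular distance is the pairwise count of differing sites, used directly
as the squared distance in the sums-of-squares decomposition. With groups
of populations, the three-level decomposition yields σ²_a (among groups),
σ²_b (among populations within groups) and σ²_c (within populations) via
the standard coefficients, and Φ_CT = σ²_a/σ²_total,
Φ_SC = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_total. Negative estimates
are retained in reports and truncated to zero only when feeding the Mantel
test. Permutation p-values permute individuals among populations (Φ_ST) or
whole populations among groups (Φ_CT) and report the plain fraction of
permuted statistics at or above the observed one; permutations that empty a
group count as exceedances (conservative).

The SAMOVA-style search anneals over surjective assignments of locations to
K groups: the neighbour move reassigns one location (rejecting moves that
empty a group), the initial temperature is the objective's standard
deviation over 100 random partitions, cooling is geometric down to 10⁻³ of
the initial temperature over 2,000 steps, and the best state over 10
restarts is kept. These sizes reliably reach the exhaustive optimum on the
≤ 8-location instances this problem involves (verified against full
enumeration of set partitions); larger location sets would warrant longer
schedules.

The Mantel statistic is the Pearson correlation of off-diagonal entries,
tested one-sided (positive association, the isolation-by-distance
hypothesis) by permuting the labels of one matrix; 1,000 permutations by
default. Geographic distances are haversine great circles (Earth radius
6,371.0088 km); locations without coordinates are dropped with a warning
and the entering set is reported.

## Synthetic data

The generator produces exactly the inputs the pipeline reads, with a
ground-truth sidecar (realised TMRCAs per population and global, the split
time, per-branch mutation counts, the true survival rate for age data).
Genealogies are Kingman coalescents for a haploid matrilineal locus
simulated backward in generations: with k lineages in a population of
effective female size N(t), coalescence hazard k(k−1)/(2N(t)); constant,
exponential-toward-the-present, and piecewise-constant histories are
supported, the latter two by exact hazard inversion. The two-population
history coalesces each population independently to the split time and
merges the survivors into an ancestral pool — isolation with zero
migration. The spatial mode is a structured coalescent on a line of demes
with nearest-neighbour migration (Gillespie over coalescence and migration
events), demes spaced along a meridian so great-circle distance is linear
in lattice separation.

Mutations fall as a Poisson process per branch and fragment at the
per-generation whole-fragment rate; under the default infinite-sites
placement each mutation occupies a fresh site, so Hamming distance equals
true mutation count and the network/rho oracles are exact. If a fragment
runs out of fresh sites the placement falls back to finite sites (recurrent
hits toggle the state) with a warning.

Defaults mirror the study conditions: 119 + 27 samples, 363 + 422 bp
fragments at 2.8 / 17.75 %/Mgen, a split of 287,584 generations (the
isolation-model point estimate) and effective female sizes of order 2×10⁵.
Tests and property checks run scaled-down configurations (tens of samples,
θ of order 1–5, split times of thousands of generations) chosen so that
several hundred replicates complete in seconds while keeping the moments
being tested — E[π] = θ, cross-population divergence 2μT, Fu's Fs sign
behaviour under ten-fold expansion (θ 5 → 50) and recent ten-fold
decline — in their informative regimes. A decline must be recent (here,
half a coalescent unit) to leave the positive-Fs signature; old declines
look like small constant populations.

What the synthetic data do not emulate: sequencing error, alignment
uncertainty, heterogeneity of rates across sites within a fragment,
selection, and recurrent mutation at hypervariable sites (unless the
finite-sites mode is requested). Passing tests therefore demonstrate
correctness of the estimators and searches under the stated models, not
robustness to those artefacts.

## Numerical and interface choices

Ewens allele-count probabilities use the unsigned-Stirling recursion in log
space (exact to rounding for the n ≤ a few hundred relevant here); S′ = 1
or 0 produce ±infinity Fs sentinels. Fu's significance is conventionally
called at p < 0.02; the raw quantile and the 0.05 comparison are both
reported. All stochastic stages require explicit seeds and reproduce
bit-identical outputs for a fixed seed. The bundled published occurrence
table stores per-location cell counts; totals are recomputed from cells
(the printed grand totals contain a one-count inconsistency in one column,
so the computed western sample size is 118 where the printed column totals
imply 119 — pooled western diversity prints 0.90 either way). The CLI exits
0 on success, 2 on configuration errors and 3 on data errors.

## Known limitations

- The MJ search is the published greedy heuristic: optimality on small
  binary instances is empirical (and ε-dependent), not guaranteed.
- AMOVA distances are plain site differences; gamma- or model-corrected
  molecular distances are out of scope.
- The coalescent null for Fu's Fs assumes a constant population of the
  observed θ_π; it is a null for the growth test, not a fitted demography.
- Maximum-likelihood/Bayesian tree inference, skyline reconstruction and
  isolation-with-migration fitting are deliberately outside the package;
  rho dating and net divergence are the dating instruments provided.
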