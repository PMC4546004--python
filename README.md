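# urocyon

A toolkit for two-locus mitochondrial phylogeography of gray foxes
(*Urocyon cinereoargenteus*) and island foxes (*U. littoralis*): haplotype
processing for a concatenated cytochrome-*b* + D-loop fragment, Nei
diversity and net-divergence statistics, composite-rate molecular dating
(divergence brackets and rho-based TMRCAs on median-joining networks),
Fu's *F*s against a coalescent null, AMOVA/SAMOVA spatial structure with
Mantel isolation-by-distance tests, generation-time estimation from
age-class data, and a coalescent simulator that generates all of these
inputs with known ground truth.

It is aimed at population geneticists working with small numbers of
non-recombining mtDNA fragments — scat- or museum-derived data, a few
hundred samples, a handful of sampling locations — who want the classic
desktop-tool analyses (haplotype networks, rho dating, SAMOVA) as a
scriptable, tested Python library.

## The statistics at the core

**Diversity.** Haplotype (gene) diversity uses Nei's unbiased estimator
*h* = *n*/(*n*−1)·(1 − Σ*p*ᵢ²) with Nei's sampling variance; nucleotide
diversity π is the mean pairwise proportion of differing sites (pairwise
deletion of ambiguous positions).

**Net divergence.** Between groups X and Y,
*d*_A = *d*_XY − (π_X + π_Y)/2, which strips ancestral polymorphism from a
split estimate. A Kimura two-parameter option is available; *p*-distance is
the default.

**Composite-rate dating.** Per-fragment per-site substitution rates
(% per million generations) combine into a length-weighted composite; the
per-sequence per-generation rate is μ = composite × length × 10⁻⁸. A
rho value (mean mutations separating an ancestral node from its descendant
haplotypes, with the Saillard standard deviation) converts to time as
*T* = ρ/μ generations, and to years through the generation time (default
2 years, estimated from geometric survival of adult age classes).

**Median-joining networks.** Minimum spanning networks under an ε
relaxation, augmented by quasi-median (position-wise majority) vectors —
inferred, unsampled haplotypes — until convergence, with obsolete median
vectors deleted. Edge weights are Hamming mutation counts.

**Neutrality.** Fu's *F*s = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the
Ewens sampling formula at θ = θ_π, and a p-value from constant-size
coalescent simulations.

**Spatial structure.** AMOVA variance components from pairwise site
differences give Φ_ST/Φ_SC/Φ_CT; a simulated-annealing search over
K-groupings of sampling locations maximises Φ_CT (SAMOVA), with permutation
tests; Mantel tests correlate Φ_ST with great-circle distance.

## Worked example

```python
from urocyon import composite_rate, haplotype_diversity, rho_to_time

# island fox haplotype counts (A-4, A-7, A-23)
res = haplotype_diversity([4, 5, 2])
print(f"h = {res.h:.3f} (SD {res.h_sd:.3f})")

# 363 bp coding at 2.8 %/Mgen + 422 bp control region at 17.75 %/Mgen
model = composite_rate([("cytb", 363, 2.8), ("dloop", 422, 17.75)])
print(f"composite rate = {model.composite_per_site_rate:.1f} %/Mgen")
print(f"per-sequence rate = {model.per_sequence_per_generation_rate:.3g} /gen")

# the island-fox clade sits rho = 1.5 mutations from its ancestral node
t = rho_to_time(1.5, 0.729, model)
print(f"TMRCA = {t.generations:,.0f} generations = {t.years:,.0f} years")
```

prints

```
h = 0.691 (SD 0.086)
composite rate = 10.8 %/Mgen
per-sequence rate = 8.51e-05 /gen
TMRCA = 17,633 generations = 35,265 years
```

— the island foxes carry three haplotypes at moderate diversity, and at the
two-fragment composite rate their matriline coalesces roughly 35,000 years
ago (assuming 2-year generations), an order of magnitude before the
earliest archaeological fox remains on the Channel Islands.

The same chain runs from the shell: `urocyon simulate` writes FASTA +
population-map + ground-truth files, and `urocyon haplotypes / diversity /
network / rho / samova / mantel / fs / gentime` run the individual stages.
`urocyon reproduce` recomputes every published desk-scale quantity from the
bundled occurrence table and prints a computed-vs-printed comparison.

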