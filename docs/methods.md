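# Methods

## The detection problem

A heterograft experiment sequences scion tissue that contains a mixture
of scion transcripts and a small admixture of rootstock transcripts that
crossed the graft union. Because the two genomes are congeneric
cucurbits, orthologous genes share high sequence identity, and a naive
"maps to the rootstock genome" rule would be dominated by homology
artifacts. The pipeline therefore classifies in two stages (scion first,
rootstock rescue second, with an identity margin between the two
thresholds) and subtracts anything detectable in homograft controls,
where no rootstock transcript can be present and every rootstock hit is
by construction an artifact.

## Synthetic data generator

The generator emulates the *shape* of such an experiment, not any
particular organism:

- **Gene sets.** `n_genes` ancestors are drawn i.i.d. uniform over
  {A,C,G,T} (GC 50 %) with lengths uniform in `gene_length_range`
  (default 300–1500 nt). The scion copy is the ancestor; the rootstock
  copy carries exactly `round((1 − ortholog_identity) · L)` point
  substitutions at distinct sites (default identity 0.85, the cucurbit
  ortholog ballpark). Substitution-only divergence keeps the identity
  arithmetic exact and the aligner's test surface clean; an indel-free
  reference also means the banded aligner is exercised on its design
  case. Lengths below 20 nt are rejected (the substitution count could
  not realize the identity target).
- **Design.** Two graft types × two tissues × `n_replicates` (default 3)
  = 12 libraries, mirroring the standard homograft/heterograft,
  pulp/stem layout.
- **Mobility.** Distance dependence is encoded as two scalar mobility
  factors rather than a spatial transport model — published data
  constrain only the qualitative ordering (stem, near the union, above
  pulp). Defaults: 2 % of the read pool is rootstock-origin in stem,
  0.4 % in pulp; homografts draw exclusively from scion transcripts.
  Within each pool, genes are sampled proportional to lognormal(0, 1)
  expression weights shared between orthologs.
- **Reads.** Default 50 000 single-end 100-nt reads per sample, uniform
  start positions, both strands, per-base substitution probability
  0.005, constant Phred quality set to the error rate's Phred equivalent
  (Q23 at 0.005). Optional paired-end mode reads both ends of a
  2-read-length fragment. Read names carry a reserved
  `|origin=genome|gene=id` suffix for oracle use only; a test permutes
  these tags and asserts the classification is unchanged.
- **Metabolites.** A coupled metabolite is built on the normal scores of
  the transcript's expression ranks (a Gaussian copula): target Spearman
  ρₛ maps to latent Pearson ρₚ = 2 sin(πρₛ/6), mixed with independent
  noise. `noise_sd=0` yields exactly ρ = ±1; the calibrated noise
  `sqrt(1 − ρₚ²)` attains the target on average.

What the generator does **not** emulate: splicing/isoforms, indels,
overdispersed biological replicate variation, positional quality decay,
adapter contamination, junk/unalignable reads, and genomic (intronic)
alignment. Passing tests therefore demonstrate the correctness of the
classification logic and thresholds under controlled homology and error,
not the read-mapping idiosyncrasies of real genome aligners.

One consequence of the missing junk fraction: in real accounting tables
the rescue-stage denominator (scion-unmapped reads) is dominated by
unalignable material, so the published "rootstock mapped rate" tracks
mobile abundance. Synthetic unmapped reads are almost all genuinely
mobile, which saturates that ratio; the distance effect is therefore
read off `rootstock_rate_of_clean` (rootstock-mapped / whole library),
which is the abundance estimate in both regimes.

## Classification

- Trimming follows sliding-window semantics: scanning 5′→3′ over every
  full window (width 4, mean quality 15), the read is cut before the
  first failing window's first base; reads shorter than 75 nt are
  discarded.
- Alignment is k-mer-seeded (k = 15; configurable stride over read
  positions, exhaustive by default) with banded global extension of the
  whole read against the best reference window (edlib, unit costs).
  Identity is BLAST-like: matching columns / alignment columns. Both
  strands are searched; ties break to the lexicographically smallest
  gene id, then the + strand — reproducibility over dictionary order.
- Scion "mapped" = identity ≥ 0.90 over ≥ 0.90 of the read (the genome
  aligner criterion is not published; this is a deliberate, configurable
  choice). Rescue = identity ≥ 0.95 (the published rule) over ≥ 0.80 of
  the read. Note the 0.90 stage-1 threshold absorbs a small fraction
  (~2 %) of genuinely mobile reads whose 100-nt window against the 85 %
  ortholog fluctuates above 90 % identity; this costs read-level
  sensitivity but never gene-level recovery at realistic coverage.
- Homograft subtraction is gene-level at threshold ≥ 1 read in any
  control — the strictest reading of "detected in controls"; the
  threshold is configurable. Paired fragments count once, to the mate
  with the stronger hit (ties to mate 1).
- Mapped rates are percentages rounded half-away-from-zero to 2
  decimals, matching the published table's arithmetic; the rescue-stage
  denominator is the reads submitted to that stage.
- Pre-aligned SAM input can be ingested (`align.hits_from_sam`) as an
  alternative to the built-in aligner; identity derives from NM and the
  CIGAR.

## Quantification and differential calling

FPKM[g,s] = counts · 10⁹ / (length_g · library_s). The differential
test is an exact binomial count test: conditional on a gene's pooled
count across both groups, the group-A count is Binomial(n, p₀) with p₀
the group-A share of total library size; two-sided p-values use the
minimum-likelihood rule, BH-adjusted within each comparison. This is a
deterministic, dependency-free stand-in for negative-binomial engines:
it is exact under Poisson (technical) variation but anticonservative
under strong biological overdispersion, which the Poisson-based count
simulator does not generate; with real replicates an NB engine is the
better choice. The log-fold-change uses a +1 pseudocount on mean FPKM
for stability at low counts. Enrichment is the one-sided hypergeometric
tail against the quantified-gene background (not a whole-genome
universe), BH across terms.

## Fuzzy c-means

`FuzzyCMeans` (scikit-learn estimator) alternates membership and center
updates with fuzzifier m = 1.25 (Mfuzz-like heuristic for well-separated
expression profiles), c = 5 by default, tol 1e−6 on the max center
shift, max 1000 iterations, k-means++-style seeded initialization.
Memberships are computed from distance ratios normalized by the row
minimum (no overflow near centers); a point coinciding with a center
takes membership 1 there. The objective J = ΣΣ u^m d² is non-increasing
across iterations by construction of the alternating updates. Profiles
are z-scored log₂(FPKM+1) per gene; constant rows are excluded
(clustering mean-centered shapes, they carry none). Clustering operates
on whichever columns are supplied; condition means are recommended for
few-replicate designs and are what the four-sample mode uses.

## RNA structure

The energy model is a constant −1 per allowed pair (AU/UA, GC/CG,
GU/UG) at kT = 1, minimum hairpin 3 — **not** a nearest-neighbor
thermodynamic parameter set. Loop censuses and entropy profiles are
therefore comparable across sequences folded by this package, but not
number-for-number with full thermodynamic folders (which, e.g., favor
long stacked helices and internal loops where maximum-pairing structures
accumulate bulges). Folding is O(n³) Nussinov with deterministic
traceback (prefer i unpaired, then the smallest partner). Pair
probabilities come from inside/outside recursions over Boltzmann
weights; probabilities are conserved per position to 1e−9 by
construction and verified against exhaustive structure enumeration for
n ≤ 12. The partition function is unscaled: beyond ~1400 nt (and a hard
cap of 2000) it overflows double precision and the call errors rather
than degrade; the outside pass also costs O(n⁴)/vectorized, so candidate
folding is intended for transcript regions of a few hundred nt (the
acceptance run folds a 240-nt 5′ region). Entropy is reported in nats
(base e). T→U and case normalization are applied on input.

## Correlation networks

Spearman rho is the Pearson correlation of mean ranks (scipy's
implementation; an independent rank-then-Pearson oracle lives in the
tests). Constant profiles give NaN and contribute no edges. The default
edge threshold is |ρ| ≥ 0.9 (no published cutoff exists; at this
package's profile lengths a p-value filter would be meaningless and none
is applied). Replicate-level profiles (up to 12 points) are the default
granularity; with four condition means the attainable rho values
collapse to eleven points (±1, ±0.8, … 0 — enumerable via
`attainable_rho_values`), which is why condition-mean networks should be
read qualitatively. Pathway subnetworks retain edges whose two endpoints
both carry a requested tag.

## Problem sizes in the acceptance run

The acceptance script uses the generator's default 12 × 50 000-read
design for three seeds (mobile recovery, distance effect), 20 + 10 count
simulations of 200 genes for the differential caller, 50 sequences of
≤ 12 nt for the enumeration oracles, and 10 replicate metabolite
couplings; these sizes give stable estimates while keeping a laptop run
in the minutes range. The test suite repeats the pipeline at 10 seeds.

## Known limitations

- The aligner is transcript-level and ungapped in spirit (unit-cost
  bands); it does not model spliced or genomic alignment,
  multi-mapping resolution, or quality-aware scoring.
- The binomial DE test ignores biological overdispersion (see above).
- The structure module's counts are model-specific; only the taxonomy
  and probability machinery transfer to thermodynamic folders.
- Homograft subtraction at threshold 1 is maximally strict; with deep
  real libraries a count or expression threshold may be preferable, and
  the parameter exists for that reason.
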