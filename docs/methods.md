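# Methods

## Model and procedure

`motifnet` scores each gene of a co-expression network for the evidence
that it belongs to an expression module regulated by a given promoter
motif, using two independent statistics computed on the gene's
**neighborhood group** — the gene plus every gene directly connected to it.

**Enrichment.** With M group promoters, m of them containing the motif, and
k of K genome-wide promoters containing it, the pValue is the upper
hypergeometric tail P(X ≥ m) with X ~ Hypergeom(K, k, M). K is the size of
the *whole* promoter dataset, not the number of network genes: the genome
is the reference population the group is drawn against. Evaluation goes
through `scipy.stats.hypergeom.sf`, which works in log space; the test
suite checks it against exact integer enumeration to 1e-12 for all
populations K ≤ 40.

**Position bias.** All n motif occurrences in the group's promoters are
pooled as midpoints p₁…pₙ on the TSS-anchored axis (0 at the TSS, negative
upstream; the last base of each stored sequence abuts the TSS). Under the
null an l-bp motif sits uniformly in an L-bp promoter, so its midpoint is
uniform on [−L + l/2, −l/2] with mean μ₀ = −L/2 and standard deviation
σ₀ = (L − l)/√12, and z = (p̄ − μ₀)√n/σ₀. The continuous-uniform variance
is the default; the discrete correction ((L−l+1)² − 1)/12 is available via
`discrete=True` and differs by ~0.1% at L = 1000. A single nominal L is
used even when individual promoters are truncated; promoters shorter than
2l are excluded from position pooling (their positions are too constrained
for the null to apply) but still count toward M and m.

**Midpoint convention.** Counting bases 1, 2, … upstream from the TSS, a
window covering bases i_first…i_last has midpoint −(i_first + i_last)/2;
even-length motifs therefore get half-integer midpoints (a window occupying
the 6 bases abutting the TSS has midpoint −3.5). Minus-strand hits get the
midpoint of their plus-strand coordinates, since distance to the TSS is
strand-free. Overlapping occurrences are all counted — the z-score needs
every instance. Scanning matches both strands by default (`strand_mode`
switches to forward-only); motif-bearing regulation is generally
strand-agnostic, and a palindromic motif simply yields two hits per site.
An `N` in the sequence matches nothing, including the motif wobble `n`:
unknown sequence is conservatively treated as motif-free.

**Selection and modules.** Seeds are genes passing an *inclusive* cutoff —
pValue ≤ c or z ≥ c. For borderline z-scores an optional
`min_instances_rule = (z_low, z_high, n_min)` requires at least n_min
pooled instances inside [z_low, z_high); with several motif variants a gene
is selected if any variant passes (OR semantics). The sub-network is the
subgraph induced on exactly the seeds — no neighbor augmentation — and
modules are its connected components with at least `min_size` genes
(default 5), labeled by their highest-degree member (ties broken
lexicographically). Components are the parameter-light, reproducible
surrogate for reading dense groups off a force-directed layout by eye.
Because a handful of spurious edges can bridge genuinely distinct dense
groups into one component, `detect_modules(refine_above=s)` optionally
splits components larger than s by greedy modularity maximization; it is
off by default and used in the recovery benchmarks (see below).

**Term enrichment.** Annotation-term over-representation in a module
reuses the same hypergeometric tail with the module as the draw. The
universe defaults to the degree-filtered network genes — the population
actually tested — switchable to all annotated genes. Raw pValues are
reported; Benjamini–Hochberg is an optional extra column, since error
control in this design comes from the permutation FDR, not from per-gene
multiplicity correction.

**Permutation FDR.** Each replicate shuffles every promoter within itself
(exactly preserving per-sequence base counts) and then reassigns the
shuffled sequences to gene ids by a uniform bijection over the *entire*
promoter set, destroying all motif signal while keeping composition and
network structure intact. The pipeline is re-run per replicate and
FDR = mean(replicate count)/observed count, at the gene and module level,
with no smoothing — so null datasets can legitimately produce FDR > 1. An
observed count of zero makes the gene-level FDR undefined and raises.
Default replicate count is 15.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `pcor_threshold` | 0.05 | minimum \|partial correlation\| for an edge |
| `min_degree` | 5 | degree floor for scored genes |
| `cutoff` | 0.001 (pValue) / 3 (z) | inclusive seed cutoffs |
| `min_module_size` | 5 | component size floor |
| `n_perm` | 15 | permutation replicates |
| `strand_mode` | both | scan both strands |
| L | 1000 bp | nominal promoter length |

The stringent cutoffs (pValue ≤ 0.001, z ≥ 3) suit well-localized motifs;
degenerate motifs may need relaxed cutoffs (e.g. pValue ≤ 0.01, z ≥ 2.2
with `min_instances_rule=(2.2, 3, 5)`), at the cost of a higher module-level
FDR — which the permutation machinery quantifies.

## Synthetic data

`motifnet.simulate.generate` draws the datasets all statistical claims are
tested on. Background promoters are i.i.d. bases at A/T = 0.33,
C/G = 0.17 (AT-rich plant promoter composition); the network is
Erdős–Rényi at p_background = 0.002. Planted modules (default three of 20
genes among 2,000) add within-module edges at p_module = 0.4 and plant
Poisson(λ = 2) motif instances per member promoter, with positions either
uniform (enrichment-only regime) or with the 3'-end distance from the TSS
drawn from an exponential of scale τ = 100 bp truncated at L − l
(position-bias regime; a one-parameter severity dial, since only the
qualitative pull toward the TSS is modeled). Edge weights are drawn above
the pcor threshold and are carried but unused by the statistics, matching
the topology-only design. The ground truth records module membership and
planted midpoints; planted instances may coincide with spontaneous
background matches, so recovery is always judged on gene-level membership,
never per-hit identity.

What the generator does *not* emulate: real expression covariance (edges
are planted directly, not inferred from expression), promoter base
heterogeneity (CpG-like tracts, TATA regions), motif co-occurrence
structure, and truncated promoters. Passing the recovery tests therefore
shows the pipeline's statistics and plumbing are correct under the model's
own assumptions, not that any particular biological network will yield
modules at these rates.

Under the default planted conditions the expected number of direct
background edges between two planted modules is ≈ 0.8 per pair (≈ 2.4
across three modules), so the seed-induced sub-network usually arrives as
one bridged component; the recovery benchmark and the acceptance script
therefore call `detect_modules` with `refine_above=30` (1.5× the planted
module size), recovering ≥ 2 of 3 modules at Jaccard ≥ 0.5 across seeds.

## Numerical and degenerate-input choices

- pValue with m = 0 is exactly 1; z with n = 0 is NaN (no evidence, not
  zero evidence). Selection never picks NaN z.
- Duplicate network edges keep the largest |pcor|; self-loops are dropped
  with a warning; seeds missing from the network are dropped with a
  warning; an empty seed set is a valid, empty sub-network.
- FASTA records with identical raw ids are a hard error; distinct
  transcript models collapsing to one locus keep the first and warn.
- Module ordering (size desc, then label) and hit ordering (5'→3', `+`
  before `-`) are fully deterministic; every stochastic stage requires an
  explicit seed, and permutation replicates use spawned child seeds so
  results are reproducible bit-for-bit from (inputs, seed).

## Problem sizes

The test suite and acceptance script run the full pipeline at 2,000 genes
× 1-kb promoters with 10–15 permutation replicates, and oracle checks at
populations K ≤ 40 — sizes at which every check completes in seconds while
leaving all statistical behavior at realistic magnitudes (hundreds of
scored genes, dozens of seeds). The pipeline itself scales linearly in
total promoter length and in network edges; genome-scale inputs (tens of
thousands of 1-kb promoters, ~10⁵ edges) run in minutes.

## Known limitations

- Consensus-word matching only; no PWM scoring, no mismatch tolerance.
- Module calling assumes seed-induced components approximate visually
  separable dense groups; very permissive cutoffs produce hairballs that
  need `refine_above` or external layout inspection.
- The within-promoter shuffle preserves mononucleotide composition only;
  dinucleotide-preserving shuffles are not implemented.
- GO-style annotation is a flat gene→term map; no DAG propagation.
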