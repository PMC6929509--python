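# Methods

## The model

`tiergene` is a generalized hidden Markov model (GHMM) gene finder for
compact eukaryotic genomes whose exon states are tripled by GC tier.  In
grasses, many genes show a steep 5′→3′ decrease in exon GC content; a
single exon model fitted to the pooled corpus averages GC-rich first exons
against GC-poor last exons and fits neither.  Here every exon role —
single, initial, internal, terminal, each reading-frame variant, both
strands — exists in three copies (high/medium/low GC), each with its own
place in the transition graph, so a gradient gene decodes as a path that
enters through a high-tier exon state and leaves through a low-tier one.
The canonical state set has **79 states**:

- 1 intergenic state (IR), emitting one base per step with a self-loop;
- 48 exon states (24 per strand: 3 single + 3 terminal/initial + 9 initial/
  terminal phased + 9 internal phased, tiers × phases × roles), each an
  explicit-duration segment state with a length distribution;
- per phase and strand: a donor window state, an acceptor window state and
  a three-part intron length device (explicit-length short intron; fixed
  d-nt prefix; geometric one-base-at-a-time tail).

Collapsing each tier triple to one state yields the 47-state single-tier
baseline used for ablation comparisons; it shares all machinery.

### Phase convention

A phased forward exon state carries the position of the exon's last base in
its codon, i.e. the cumulative coding length mod 3; downstream non-exon
gene states carry the preceding exon's phase.  The reverse strand is
decoded left-to-right in genomic coordinates (3′→5′ along the transcript);
a reverse exon state carries the transcript phase at which the exon is
*entered* in transcript order.  Under this convention reverse terminal
exons are phased and reverse initial/single exons are not, and frame
consistency across an intron reduces to a residue constraint on segment
lengths: an exon of length ℓ entered at phase *i* exits at phase
(*i* + ℓ) mod 3 (forward) or is entered from a donor-phase state *x* with
ℓ ≡ *x* − *y* (mod 3) (reverse internal exon of exponent *y*).

### Emissions

- **Coding exons**: one inhomogeneous k-th order Markov chain per GC tier
  (default k = 4), with a conditional table per codon position and
  lower-order fallback tables for positions whose left context is truncated
  by a sequence boundary or an ambiguous base.  The chain is shared across
  exon roles and strands; reverse-strand segments score the reverse
  complement in transcript orientation.  Contexts at a segment start use
  the actual preceding genomic bases (transcript orientation), which makes
  segment scores prefix-summable in the decoder.
- **Introns and intergenic sequence**: homogeneous chains (default k = 4).
  The intergenic chain is direction-aware: its reverse-complement mirror is
  a right-context chain, which is what makes the strand mirror exact (see
  below).
- **Splice sites**: positional weight matrices over fixed, fully intronic
  windows — donor = GT + 3 context bases (W = 5), acceptor = 21
  branch-region bases + AG (W = 23), both configurable.  The GT / AG
  consensus positions are hard constraints (−∞ on mismatch); GC–AG and
  other minor splice classes are rejected.
- **Hard coding constraints**: initial/single exons must start with ATG,
  terminal/single exons must end with a stop codon, and complete in-frame
  stop codons are forbidden inside a coding segment.  These constraints
  make exon emission distributions deliberately *deficient* (they sum to
  less than one over all sequences), as is usual in GHMM gene finders; the
  unconstrained Markov emission sums to exactly one.
- `N` emits 1/4 from every state and truncates Markov contexts.

### Length model

Exon length distributions are empirical histograms per (role, tier),
smoothed by a triangular kernel (default bandwidth 10 nt) and renormalized
on [1, `max_exon_len`] (default cap 3000 nt; minimum lengths 6 nt for
single exons, 3 nt otherwise).  Introns use the three-part device: an
interior of at most `d` nt (default 40) is emitted by the explicit-length
short-intron state (empirical distribution on [1, d]); longer interiors
are a fixed `d`-nt window followed by a geometric tail whose self-loop
probability is estimated from the observed tail lengths.  For reverse
introns the fixed window sits at the genomic left (acceptor) end — the
mirror image of the forward layout; both parts emit from the same
homogeneous chain, so the placement is likelihood-invisible.

## Training

Genes failing structural validation (no ATG, missing stop, non-GT..AG
intron, in-frame stop, intron shorter than the combined splice windows,
region-boundary contact, overlap with the previous gene) are skipped with a
logged reason, never repaired.  Valid exons are classified into tiers by
two GC cutoffs: GC < `lowT` → low, GC > `highT` → high, otherwise medium
(boundaries are medium; the inequalities are strict).  Each gene then
implies one deterministic state path, and transitions are counted along it
(including per-base self-loops of the intergenic and geometric-intron
states).

Two estimation strategies:

- **mle** — maximum likelihood with pseudocounts on the tiered state set:
  a_kl = (A_kl + r) / Σ_q (A_kq + r), Laplace r = 1 by default.  A state
  never observed falls back to a uniform row.
- **equal** — a tier-blind matrix is estimated on the collapsed 47-state
  set, then every edge into a tier triple is divided equally among the
  three tier states and rows out of a triple are replicated.  This is the
  scarce-data strategy: it starts the tier states from single-tier
  transition estimates.  Splitting followed by collapsing is an exact
  round trip (tested to 1e-12).

A transition-coverage report lists all legal edges observed fewer than a
threshold (default 5) number of times; it operationalizes the guidance to
pick (lowT, highT) so that the training corpus covers every transition,
since an edge observed zero times is carried by its pseudocount alone.
K-fold cross-validation (default 10 folds) shuffles *regions* with a fixed
seed, holds each fold out once, and grid-searches (lowT, highT) by mean
exon-level (Sen+Spe)/2; ties go to the smallest cutoff pair.

## Decoding

A single duration-explicit Viterbi pass over both strand halves.  For each
end position and explicit-duration state the decoder maximizes over legal
segment lengths using precomputed cumulative emission arrays; the frame
alignment of an exon state at a fixed end position is constant over
durations, and in-frame stop-codon bookkeeping reduces to next/previous
stop tables per frame, so each cell is a vector operation.  Complexity is
O(|Q| · L · D) with D the duration cap — the linear-in-L behaviour of a
standard HMM holds only because durations are bounded, which the cap makes
explicit.

The parse starts in IR with probability one and must end in IR, so only
complete genes are reported (no partial genes at region boundaries).  Ties
break deterministically: shortest duration, then lowest state ordinal.
Every reported gene satisfies the hard constraints by construction, with
one documented exception: a stop codon *split across an intron* is not
representable in the state space without enlarging the intron states (the
classical remedy is to push the split-codon bases into the splice windows),
so the decoder cannot exclude it; the synthetic generator rejects such
genes, and on realistic emission contrasts the configuration is rare.

### The strand mirror

For testing, `mirror_model` constructs the model under which decoding the
reverse complement reproduces every parse score exactly.  A naive swap of
the two strand halves is not row-stochastic for a trained matrix.  The
exact construction reassigns each trained edge through the path
correspondence induced by the phase convention (e.g. the mirrored edge
IR → rE_term^x corresponds to ASS^x → E_term), then multiplies each edge by
φ(head)/φ(tail), where φ is the Perron eigenvector (eigenvalue 1) of the
raw reassigned matrix.  The gauge factor telescopes along every
IR-to-IR path, so all path probabilities are preserved, while rows become
stochastic again.  Emissions need no adjustment except the intergenic
chain, which is replaced by its reverse-complement (right-context) form.

## Evaluation

Sensitivity TP/(TP+FN) and specificity TP/(TP+FP) at three levels, with the
two strands treated as separate sequences for base counting: coding-base
overlap (base level); exact coordinate match of both exon boundaries, the
same rule for all exon roles (exon level); exact match of the entire exon
chain with no extra exons (gene level).  Zero denominators give NaN, never
0.  For tool comparisons, correctly predicted truth genes are partitioned
into unique-to-A / unique-to-B / common, each summarized by mean
*GC-distance* (max − min of the per-exon GC profile) and mean per-gene
population SD of that profile — genes with strong internal GC
heterogeneity have large values of both.

## Synthetic data

The generator emulates the one property the tier states target: per-gene
exon GC profiles that either fall 5′→3′ (default 0.70 → 0.35 linearly
across exons) or sit flat at a high (0.68), medium (0.50) or low (0.37)
level, on a 0.35-GC intergenic background, half of all genes carrying the
negative gradient by default.  Genes are multi-exon (3–5 exons of
60–210 nt, introns of 50–120 nt, both strands equally), with ATG starts,
GT..AG introns, closing stops, and no in-frame stops — including stops
split across introns, which are removed by composition-preserving base
swaps.  Exon base composition is drawn with *exact* G+C counts, so each
exon lands within rounding distance (≪ ±0.03) of its target, and the G+C
mass is skewed toward the third codon position (±0.15 by default),
mirroring the GC3-driven gradients of real grass genes and giving the
coding chains a learnable period-3 signal.

What the generator does **not** emulate: real codon usage and hexamer
statistics, UTRs, alternative splicing, repeats, pseudogenes, GC-content
autocorrelation within exons, and realistic splice-site motifs beyond the
GT/AG consensus (the branch region is compositionally flat).  Passing the
benchmark therefore shows that the tiered architecture recovers
GC-gradient genes *when composition is the discriminating signal*; it does
not certify performance on real genomes, where splice and codon-usage
models carry much of the information.

A second generator samples gene *structures* directly from a model's
transition matrix and length distributions (gaps from the intergenic
self-loop, short-intron interiors from the explicit distribution, long
interiors as prefix + geometric tail) and realizes them with mid-tier GC
targets so that tier labelling recovers the sampled states exactly; it
drives the parameter-recovery experiment.

## Problem sizes and numeric choices

- Gradient benchmark: 150 training regions and 24 test regions of 4 kb with
  2 genes each, cutoffs (0.45, 0.60), duration cap 300 nt, d = 40 — the
  training scale matches the corpus sizes typical for this kind of model
  (hundreds of regions) and keeps a full train+decode cycle in minutes.
- Parameter recovery: 4000 genes sampled from a designed non-uniform
  matrix; with row counts in the thousands the binomial standard error of
  every edge with ≥ 200 traversals sits well inside the ±0.02 band.
- Decoder optimality: 200 sequences of ≤ 30 nt against exhaustive
  enumeration with reduced caps (windows 2/2, d = 3, exon cap 12, k = 0).
- Row-stochasticity is enforced to 1e-9; parse re-scoring agrees with the
  dynamic program to better than 1e-6 (typically 1e-10); the equal-split
  round trip is exact to 1e-12.
- Model files are JSON with full float round-trip precision; write → read →
  write is byte-identical, and training is deterministic, so identical
  corpora yield identical model files.

## Known limitations

- No UTR or promoter states: predictions are CDS-only.
- Complete genes only; genes truncated by a region boundary are neither
  predicted nor modelled.
- Split-codon stop exclusion is not enforced across introns (above).
- The acceptor branch-point region is modelled positionally, not by a
  dedicated branch-site submodel.
- Tier cutoffs are global constants per model; no per-isochore adaptation.
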