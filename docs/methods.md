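# Methods

## Problem setting

Metagenomic fragments of a few hundred nucleotides carry too little
data to train a species-specific gene model, yet single-nucleotide
indels — primarily sequencing errors that survive assembly — shift the
reading frame of protein-coding genes and corrupt downstream analysis.
`fsfinder` detects such frameshifts ab initio: all model parameters for
a fragment are reconstructed from its GC content alone.

## Heuristic polynomial model family

Prokaryotic oligonucleotide usage varies smoothly with genome GC. The
family stores, for every hexamer, a degree-5 polynomial of its relative
frequency against genome GC percent θ — separately for the three codon
phases of coding DNA (the phase of a hexamer is the codon position of
its last base) and once for non-coding DNA. Training counts phased
hexamers over annotated CDS (minus-strand CDS reverse-complemented
first) and non-coding hexamers over the complement of all CDS, with a
+1 pseudocount per cell, and fits each frequency-vs-θ curve by ordinary
least squares. Fitting requires at least degree+2 genomes spanning at
least 20 GC percentage points (degree 0 — the plain mean — is exempt,
so a single-genome family is possible for testing and for
species-specific use).

Polynomials are fitted on *frequencies*; conditional next-base
probabilities are derived at instantiation time: evaluate every
polynomial at the fragment's θ (clamped to the fitted range — constant
extrapolation outside it), clamp frequencies to [10⁻⁶, 1], renormalize
within each 5-mer context, and take logs. Every conditional therefore
sums to exactly 1 regardless of fit error, which the tests verify to
1e-9 across random θ.

## Frame-aware HMM and decoding

Seven states: non-coding (NC) and coding-in-frame C(f, s) for
f ∈ {0,1,2} on each strand. Durations are geometric with means
`mean_noncoding_len` = 150 nt and `mean_coding_len` = 900 nt (typical
prokaryotic intergenic and gene lengths); the per-nt exit probability
of a state is the reciprocal of its mean. Inside a gene a frame switch
to either alternative frame on the same strand occurs with prior
probability `p_fs`/2 each per coding nt (default p_fs = 10⁻³, a rate in
the regime of residual indel errors in assembled metagenomic data);
strand changes must pass through NC. p_fs must stay below the coding
exit probability 1/`mean_coding_len` so the transition budget is
consistent. The initial distribution is duration-proportional.

Emissions: in C(f, +), position i emits its base through the coding
conditional at phase (i − f) mod 3 given the preceding 5-mer;
minus-strand coding states score the reverse complement (a 5-base
lookahead on the forward sequence — legal because Viterbi only needs a
per-position score matrix). There are no explicit start/stop-codon
states; instead the last base of an in-frame stop triplet incurs a
penalty of −25 nats (config), the smallest architecture in which
"frameshift = in-gene frame transition" is well defined. The NC score
is the mean of the forward and reverse-complement background scores,
which makes the full model exactly strand-symmetric: decoding the
reverse complement provably yields the mirrored path (ties aside), and
the tests assert it exactly. Positions without a full A/C/G/T 5-mer
context — the first five, or any window containing N — fall back to the
uniform background log ¼ in every state, so they cannot influence the
path.

All arithmetic is in log space; Viterbi ties resolve deterministically
(NC first, then lower frame, then + strand, via the state ordering).
Viterbi optimality is checked against exhaustive enumeration over all
hidden paths on toy state spaces with integer-valued scores, where
float64 sums are exact and the comparison is literal equality.

A frameshift call is located at the last nt decoded in the upstream
frame (on minus-strand genes: the segment that comes first in reading
order). The 20-nt true-positive window of the benchmark absorbs the
difference between this convention and the indel nucleotide itself.
Frame change Δ = (downstream − upstream) mod 3 maps to +1
(insertion-like: an inserted base advances the apparent frame) or −1
(deletion-like). The call's score is its Viterbi margin: total Viterbi
log-probability minus that of the best path with frame-switch
transitions banned inside the containing gene's interval (a second,
position-masked decode). The margin is non-negative by construction and
shrinks monotonically as p_fs decreases.

## Two-step pipeline

Step 1 decodes each fragment with p_fs = 0 — a pure gene finder — using
the model instantiated at the fragment's GC. Its gene calls partition
the fragment into maximal same-strand regions (consecutive same-strand
genes share one region: a frameshifted gene looks like two adjacent
same-strand genes to the zero-switch decoder, so splitting between them
would hide the very switch step 2 must find; boundaries fall at
midpoints between opposite-strand neighbours, which reflect exactly
under reverse complementation). Step 2 re-decodes each region,
strand-normalized, with p_fs > 0, applies the filters and maps calls
back to fragment coordinates (affine for +, reflection for − regions).
Genes overlapping a surviving frameshift are replaced by the
frameshifted gene call; other step-1 genes are retained. Regions are
decoded independently — no concatenation across gaps, which could
fabricate frame continuity that is not in the data.

## False-positive filters

All three filters are evaluated on every call and recorded in
`filters_failed`; only failures of *enabled* filters remove a call, so
one run supports any filter-combination study.

* **Filter I.** A genuinely frameshifted gene spans two overlapping
  ORFs; if the downstream ORF has its own functional ribosome-binding
  site it is more likely an independent gene. The downstream start is
  the most 5′ in-frame ATG/GTG/TTG of the downstream-frame ORF at or
  upstream of the call; its RBS score is the best PWM log-odds (base 2,
  uniform background) of a 6-mer at spacer 4–12 nt upstream. Score
  strictly above 2.0 removes the call. No resolvable start, or
  truncated upstream context (−∞ sentinel), fails open. The default PWM
  is the Shine–Dalgarno consensus AGGAGG at 85% per-column consensus
  probability; both PWM and threshold are config — the score scale of
  the original filter is not recoverable, so the threshold is anchored
  to this PWM's scale.
* **Filter II** (θ > 50 only). In high-GC genomes a true frameshift
  lies far from the stop codon that terminates the upstream ORF. The
  required distance grows linearly: d_min(θ) = max(0, a·θ + b) with
  a = 2.0 nt/%, b = −60 nt (40 nt at θ = 50, 90 nt at θ = 75). The
  linear form and its constants are a documented stand-in — only the
  qualitative shape of the original rule is recoverable — and both are
  config. No in-frame stop before the fragment end fails open.
* **Filter III** (θ ≤ 50 only). Calls closer than 50 nt to a border of
  the putative frameshifted gene or of the fragment are removed. When
  step 2 decoded a sub-region, pad offsets restore distances to the
  true fragment borders.

Because II and III partition on θ, at most one of them can fire on a
fragment; filters never add or move calls. Filter order is irrelevant —
each is evaluated independently.

## Synthetic fixture genomes and what they do (not) show

The published polynomial families are trained on hundreds of real
annotated genomes and are not shipped here; instead the package
generates annotated fixture genomes so the entire method is trainable
and testable self-contained (a user-supplied FASTA + GFF3 family works
identically).

A fixture genome alternates i.i.d. non-coding spacers (mean ≈ 150 nt)
with CDS (ATG + stop-free codon body + stop; mean ≈ 900 nt; about half
on the minus strand). Codons are drawn from a 3-periodic usage model:
fixed per-position base skews (purine-rich first positions, AT-leaning
second positions) whose product weights are squared to concentrate
usage to about 29 effective codons — the bias level of moderately
expression-biased prokaryotic genes — and tilted by a per-codon factor
γ^(#GC) with γ solved (Brent) so coding GC hits its target. Intergenic
DNA is generated 10 GC points below coding DNA, as in real prokaryotic
genomes, with the coding target raised so genome-wide GC lands on the
requested θ (realized within ±2 points over θ ∈ [25, 75]). Both
features give the model family genuinely strong coding/non-coding and
phase contrast (≈0.18 nats/nt background-vs-coding divergence), which
the self-consistency tests presuppose.

What the fixture does *not* emulate: real hexamer correlations beyond
first-order codon structure, ribosome-binding sites upstream of true
starts (so Filter I fires only on chance motifs), operon structure,
GC-skew, repeats, or annotation errors. Passing tests therefore
demonstrate the machinery — model fitting, decoding, filtering,
simulation and scoring — under controlled conditions, not
field accuracy on real genomes; the benchmark harness accepts real
FASTA + GFF3 inputs for that purpose.

## Benchmark protocol

Fragments of 400/600/800 nt are sampled at uniform-random offsets (the
source protocol does not specify tiling; random placement with both
strands equiprobable is used, seeded). A fraction (5/10/20%) of
fragments — exactly round(fraction·n), selected among fragments with an
eligible site — receives one single-nt indel at a uniform position
inside a coding stretch > 200 nt, at least 50 nt from the fragment
borders; the inserted base is uniform. A prediction is a true positive
iff it lies within 20 nt of its fragment's true indel; each truth
matches at most one prediction (closest first; extra calls on the same
fragment are false positives — the source accounting does not specify
this case, so the 1-to-1 rule is fixed here). Sn = T/S, Sp = T/A
(precision); Sp is reported as NA when A = 0. Grid results are averaged
per genome and then between the insertion and deletion sets.

## Scales used and reproducibility

The test suite and `scripts/acceptance.py` train the family on ten
fixture genomes of 300 genes each (GC 30–75%), localize forced frame
switches on 200 model-sampled 600 nt fragments, verify simulator
exactness at n = 2000 fragments, and run the benchmark on two genomes ×
400 fragments × insertion/deletion at 600 nt and 20% fraction — sizes
chosen so the whole cycle completes in minutes on one CPU while keeping
binomial noise on rate estimates to a few percent. All randomness flows
through seeded numpy generators; identical seeds give byte-identical
GFF3 output.

On this synthetic world the unfiltered pipeline runs at roughly
85–90% sensitivity and 75–85% precision; enabling all three filters
raises precision further but costs sensitivity, mainly through
Filter II's stand-in distance constants and Filter III's border rule
interacting with the 50-nt placement margin. Since the original
Filter II constants are unrecoverable and no real RBS signal exists in
the fixture world, the filter defaults should be re-tuned (they are all
config) before use on real data.

## Known limitations

* One model family; the bacterial/archaeal model-type choice is exposed
  only as a structural hook (train separate families and select
  externally).
* No explicit start/stop states or RBS-aware gene starts in the HMM;
  gene boundaries are duration- and emission-driven and therefore soft.
* At most one frameshift is scored per constrained re-decode per gene;
  multiple switches in one gene share the gene's margin.
* Whether the original polynomials were fitted on frequencies or
  log-frequencies is not recoverable; frequencies are used.
* Programmed (recoding) frameshifts and read-level error models are out
  of scope.
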