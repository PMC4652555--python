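# Methods

## Problem and approach

Comparing the transcriptomes of two related organisms without reference
annotations usually means assembling each organism's RNA-Seq reads de novo
and comparing the predicted transcripts afterwards. Because de novo
assemblers resolve ambiguities with coverage information alone, transcripts
that are well supported by cross-species conservation can still be missed.
`dbgalign` takes the other route: it keeps both organisms' assemblies as de
Bruijn graphs and searches for *pairs of corresponding paths* directly,
using local-alignment significance between the two graphs as the guide. The
retained path pairs are predicted transcripts with built-in evolutionary
support; a reciprocal-hit rule then calls the subset shared by both
organisms.

## Graph model

A k-mer occurring in the reads is a vertex; a directed edge joins two
vertices when they overlap by k−1 bases **and** the joining (k+1)-mer was
observed in a read or its reverse complement. (The overlap condition alone
would admit spurious edges between chance-overlapping k-mers; requiring
read support is what short-read assemblers actually do.) Maximal branchless
chains are collapsed into single nodes. The graph is double-stranded: every
node has a *twin* carrying the reverse-complement sequence, edge sets mirror
under twinning, and a node whose sequence equals its own reverse complement
is its own twin. Isolated simple cycles (tandem repeats, homopolymers) are
linearized at a deterministic break point chosen so that twin pairing still
holds; see the module docstring for the exact conventions.

Node coverage is the mean multiplicity of the node's k-mers, pooling a
k-mer with its reverse complement. The coverage cutoff `c` removes nodes
with coverage strictly below `c` (twins go together) and re-collapses the
survivors. Defaults follow the standard protocol: `k = 25` (31 as the
stringent alternative), `c = 3` (5, 10 harder).

## Alignment statistics

Pairwise BLAST is replaced by exact local alignment (affine gaps; a gap of
length L costs open + L·extend) through Biopython's C aligner, with
significance computed from Karlin–Altschul theory:

    E = K · m · n · exp(−λ · score)

λ solves Σ pᵢpⱼ e^(λ·sᵢⱼ) = 1 over background frequencies (uniform bases;
Robinson–Robinson amino-acid frequencies), and K is computed with the
standard lattice formula K = d·λ·e^(−2σ)/(H·(1−e^(−λd))), σ being the usual
correction series evaluated by convolving the score distribution. For the
default nucleotide scoring (+1/−2, gaps 5/2) this yields λ = 1.3327,
K = 0.6210, and for BLOSUM62 (gaps 11/1) λ = 0.3176, K = 0.1338 — matching
the published ungapped constants. Gapped alignments reuse the ungapped
constants and the effective-length correction is omitted; both are
documented approximations, and every cutoff in the package is calibrated
against these statistics rather than NCBI BLAST's.

Nucleotide mode searches both subject strands. Translated mode aligns the
six reading-frame peptides of the query against the three forward frames of
the subject — the omitted subject-reverse combinations are exact mirror
images with identical scores. Stop codons score as the matrix's `*` column.
E-values in translated mode use peptide lengths (⌊n/3⌋).

All comparisons inside the package happen on the log10 e-value scale. For
near-identical sequences a few hundred bases long the e-value underflows
double precision to exactly 0.0, which would freeze any strict-improvement
rule; log-space comparisons keep full resolution at any significance.

All-vs-all stages (seeding, shared-calling, evaluation) use a BLAST-like
exact-word prefilter before running dynamic programming: pairs sharing no
word (default 12 nt / 6 aa; configurable, 0 disables) are skipped. Word
hits are symmetric in the two sequences, and so are all alignment scores
here, so each unordered pair is computed once and reused for both
directions.

## Iterative extension

For each node u of graph 1, its most similar node v of graph 2 (e-value
below the seeding cutoff, default 0.1) forms a seed. Both sides start as
single-node paths. A side grows greedily: extend the current frontier by
one node along every outgoing edge, score each candidate against *all*
retained paths of the opposing side (minimum e-value over the set), retain
every candidate that strictly improves on the frontier's e-value, and
continue from the best one; stop when nothing improves. The two sides take
turns; before each turn the frontier is re-scored against the opposing set,
which may have grown (the e-values recorded on already-retained paths are
not revised). The alternation ends when a full round retains nothing new.

Extension is forward-only. Leftward growth comes from the twin mechanism:
paths retained from a node's twin are reverse-complemented into walks
ending at the node and concatenated with the paths retained from the node
itself; a concatenation is kept when its e-value (against the union of both
seeds' opposing sets) improves on both constituents. Self-twin seeds skip
merging; concatenations that are not valid walks are skipped.

Because E grows with query length m, an extension can only improve the
e-value if the alignment itself grows into the opposing sequence. A
consequence worth knowing: if both graphs happen to break a transcript at
the same positions, neither side can improve and extension stops at the
seed nodes — progress relies on the two graphs' node boundaries differing,
which is the normal situation for independently assembled organisms.

Cycles cannot hang the search: walks are capped at 500 nodes and at 2
visits per node (both configurable). Each seed's alternation is
self-contained, so seeds run in parallel (`threads`); results are identical
to sequential execution by construction, and a strict-decrease audit of
every recorded frontier history runs on every alternation.

The full procedure runs once per scoring mode (translated, then nucleotide)
and once per seeding direction (roles of the graphs switched), and the
retained paths are pooled per graph, deduplicated by node tuple keeping the
best e-value.

## Transcript selection and shared calls

Retained paths become predicted transcripts after two greedy filters, both
in ascending e-value order (ties by node tuple): a path must contain at
least one node not covered by a better path (a node is covered by a path
containing it or its twin), and no node+twin may occur more than 10 times
(pooled, counting repeat visits individually) among the kept paths.

Shared transcripts: all predicted transcripts of one organism are aligned
against all of the other (both modes, both directions) at the reciprocal
cutoff (1e-7 default, 1e-20 stringent). A transcript is called shared when
it has at least one hit as a query and appears at least once as a subject
of the other organism's hits; a hit in either mode counts. With symmetric
scoring the two conditions coincide; they are tracked separately anyway.

## Synthetic data

The simulator generates ancestral transcripts uniform over {A,C,G,T} with
lengths uniform in 600–1200 bp, then derives each organism's copy by
substitutions at divergence/2 and 1–3 bp indels at indel_rate/2 per base,
so the *pairwise* divergence between copies matches the configured value —
the quantity the robustness sweep varies. Private transcripts are independent
random sequences. Reads are single-end, drawn uniformly along each
transcript from both strands at the configured depth, with constant Q40
qualities and optional per-base substitution errors; everything is
reproducible from one integer seed. Randomness is organized into keyed
substreams per transcript, with draw shapes independent of the rates:
simulations at different divergence settings therefore share ancestors,
indel layouts and read positions, and their substitution sets are nested
(common random numbers). That coupling is what makes monotone comparisons —
recall as a function of divergence — meaningful at a single replicate.

Defaults encode the standard study conditions used by the acceptance
experiment: 50 shared + 10 private transcripts per organism, 2% divergence,
0.001 indel rate, 100 bp error-free reads at 20x. Error-free reads keep the
acceptance surface sharp; the error model and quality trimming (truncate at
the first base with quality < 15) are exercised by their own tests. What
the simulator deliberately does not model: expression-level variation,
paired ends, alternative-splicing isoforms, and composition bias. Passing
tests therefore demonstrate recovery of diverged shared sequence under
uniform coverage, not robustness to real library artifacts.

## Evaluation

Predicted shared transcripts are aligned (nucleotide mode) to the
ground-truth *shared* sequences of their organism, each call contributing
its best alignment. Precision is the fraction of call positions inside
those alignments; recall is the fraction of truth positions covered (per
truth sequence, overlapping subject ranges are unioned); the F-score is
their harmonic mean. Positions are pooled across sequences
(micro-averaged; macro available). A truth transcript counts as recovered
at 80% full length when some call's best alignment covers ≥ 80% of its
length. The truth database contains only the shared transcripts — private
ones are unrecoverable by construction and are instead used to audit false
shared calls (a call whose closest true sequence is private).

## Numerical and design choices

- Strict improvement everywhere: equal e-values never extend, retain, or
  merge. Comparisons are exact float comparisons on log10 e-values.
- Tie-breaks are always lexicographic (candidate/partner id, node tuple,
  appended node id), making runs bit-reproducible.
- Node ids are assigned in lexicographic order of the canonical (smaller of
  forward/reverse-complement) contig sequence.
- The coverage cutoff is a strict less-than; `c = 0` is a no-op up to
  re-collapse.
- Reads with non-ACGT characters are split at the ambiguous bases; fragments
  shorter than k are dropped.
- Degenerate inputs: an empty or all-short read set raises a dedicated
  error at the library level and produces clean empty outputs with a
  warning at the pipeline level.

## Problem sizes

The test suite and the acceptance script run the full study conditions
(50+10 transcripts per organism, ~11,000 reads each) end to end — about two
minutes per run on one core — plus oracle batteries at small scale: 100
random read sets against the brute-force graph, 500 random pairs against
the substring-enumeration aligner, and 50 planted extension instances
against exhaustive walk search.

## Known limitations

- Non-coding and poorly conserved regions extend weakly: the method can
  only follow sequence that aligns across the organisms.
- Transcripts private to one organism are (by design) never extended or
  called; the pipeline reports them only as ordinary predicted transcripts
  when a chance seed exists.
- E-value statistics use ungapped λ/K with gapped alignments and raw m·n;
  cutoffs are therefore internally consistent but not comparable to NCBI
  BLAST numbers.
- The greedy frontier is optimal only when each junction's correct
  successor strictly improves the e-value (the planted-instance property);
  adversarial graphs can mislead it, which is inherent to the heuristic.
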