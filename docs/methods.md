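# Methods

## Model and procedure

ampliswarm clusters dereplicated amplicons (unique sequence + read count)
into OTUs by iterative growth rather than by a global identity cutoff.
An OTU is an edge-weighted rooted acyclic graph: the root is the seed
(the most abundant unassigned amplicon), every other member records the
parent that claimed it, the verified distance of that link (≤ t) and its
generation (links from the seed are generation 1, and so on). Growth is
breadth-first: all partners of the current generation's members are
attached before the next generation is explored; the OTU closes when a
generation stays empty, and the next seed starts a new OTU until the
pool is exhausted.

With the breaking rule enabled (default), a partner is only attached if
the subseed's abundance is at least the partner's, so abundance is
non-increasing along every root-to-leaf path. Equal abundances may chain
indefinitely (the comparison is ≥, not >), which permits plateaus of
equal-abundance amplicons inside one OTU.

The pipeline has three phases: preprocessing (length/alphabet filtering,
dereplication, abundance ordering, pooling), per-pool clustering, and
the optional fastidious refinement followed by output generation.

### Pooling

Any alignment of two sequences whose lengths differ by g contains at
least g gap columns, so both distance modes are bounded below by the
length difference. Splitting the input wherever consecutive observed
sequence lengths differ by more than t therefore yields pools that
cannot exchange members at threshold t and are clustered independently;
final OTUs are reported in the global priority order of their seeds, so
pooling is invisible in the output. This holds in both distance modes,
and the fastidious step (threshold t_f > t) ignores pool boundaries.

### Candidate generation (segment filter)

For threshold tau, each indexed sequence of length l is cut into
tau + k contiguous segments (k ≥ 1, default k = 2) whose lengths differ
by at most one, longer segments last. tau edits can touch at most tau
segments, so a sequence within distance tau shares at least k segments
exactly with the query (generalised pigeonhole). Candidates are found by
probing inverted indices I(l, i) — (length, segment index, segment
string) → identifiers — with selected substrings of the query:

* k = 1: the tight multimatch-aware windows; for segment i at position
  p_i, query starts are limited to
  [max(0, p_i − (i−1), p_i + Δ − (tau+1−i)),
  min(|S| − l_i, p_i + (i−1), p_i + Δ + (tau+1−i))], Δ the length
  difference.
* k > 1: the tight generalisation is not used; windows are relaxed to
  ±tau around the (Δ-shifted) segment position. This over-selects but
  never misses a true pair — completeness is the property everything
  downstream relies on, and is what the test suite checks exhaustively.

Because the relaxed k > 1 windows over-select, candidate sets for k = 2
are not always subsets of those for k = 1, and candidate sets at tau+1
do not always contain those at tau (the partitions differ); both
containments do hold for the pairs that are truly within threshold.

A bidirectional second stage re-runs the check with the roles of query
and candidate swapped, discarding more spurious candidates before
verification. Sequences shorter than tau + k cannot be partitioned; they
are kept in a side list, returned for every length-compatible query and
left to verification.

All indices of a pool are built up front (processing order is by
abundance, not by length). The fastidious step builds a second index at
t_f containing only light-OTU amplicons, queried by heavy-OTU amplicons.

### Verification

Candidates are verified by bounded DP restricted to the diagonals
c = j − i with |c| + |c − Δ| ≤ tau (at most 2·tau+1, fewer when the
lengths differ), since reaching diagonal c and returning to the final
diagonal Δ costs at least that many gap columns.

* Edit-distance mode: banded Levenshtein DP; stops early once every
  active cell exceeds tau; returns the exact distance iff ≤ tau.
* Scoring-function mode: banded three-state (Gotoh) DP under the affine
  scoring function; a gap of length g costs open + g·extend (the opening
  column is also charged extension). d_δ is the number of difference
  columns (mismatches + gapped columns). Among co-optimal alignments the
  minimum difference count is reported, computed by carrying
  (score, −differences) pairs through the recurrence and comparing them
  lexicographically. This choice — rather than the count of one
  traceback-canonical alignment — keeps d_δ symmetric in its arguments
  and independent of implementation details; it is the reading used
  throughout. Early termination uses the accrued difference count plus
  the unavoidable residual length imbalance as a lower bound.

The same edit-distance segment filter front-ends both modes: the number
of differences in an optimal alignment is bounded below by the edit
distance's filter criterion, so no d_δ-partner is lost.

### Fastidious refinement

OTUs with total abundance (weight) below the boundary b are light, the
rest heavy (defaults b = 3, t_f = 2·t; any t_f ≥ t+1 is accepted —
t_f = 2·t corresponds to one virtual linking amplicon at distance t from
each side, t_f = t+1 is the conservative setting). Grafting links (h, l)
with d(h, l) ≤ t_f are found by the second segment filter and verified
in the same mode as the main clustering. Per light amplicon only the
most abundant heavy partner is kept (ties: lexicographically smaller
id); links are applied in order of heavy abundance desc, then light
abundance desc, then ids; a light OTU is grafted at most once. On a
graft, the light OTU's member tree is re-rooted at l (its internal links
are preserved, reoriented towards l), l becomes a child of h at the link
distance and generation gen(h)+1, and the whole subtree moves into the
heavy OTU. The virtual amplicon itself is never materialised.

## Determinism and tie-breaking

All orderings derive from one priority: abundance descending, then id
ascending, then input rank. Seeds, subseed exploration within a
generation, partner attachment, OTU output order and residual link ties
all use it, so shuffling the input records changes nothing in any output
file (ids are unique after dereplication, so input rank never decides).
First claim wins when two same-generation subseeds reach the same
amplicon. Dereplication keeps the id of the most abundant merged member
(ties: earliest input rank).

## Parameters

| parameter | default | meaning |
|---|---|---|
| t | 1 | local clustering threshold (differences per link) |
| mode | edit | d_e, or d_δ under δ ("score") |
| δ | 5/4/12/4 | match reward, mismatch, gap-opening, gap-extension |
| breaking | on | abundance-monotone links |
| k | 2 | extra segments; k=1 = classic Pass-Join filter |
| t_f | 2·t | fastidious threshold (≥ t+1) |
| b | 3 | light/heavy OTU weight boundary |

k trades filter strength against probe count: more segments filter more
sharply but cost more lookups per query; both k=1 and k=2 are complete.

## Synthetic mock communities

The generator emulates a mock community: n_species random centroids
(default 50, length 250, pairwise edit distance ≥ 20 — roughly the
inter-species divergence of a short 16S variable region), per-species
read counts drawn log-normally (default meanlog 4.0, sdlog 1.5: a few
abundant, many rare species, the skew typical of fitted soil-community
profiles), and reads derived from their centroid with per-base error
rate 0.005 (≈ 1.25 errors per 250 bp read, an amplicon-sequencing error
scale), 10% of errors being indels. Identical reads are dereplicated
with summed abundance; each unique amplicon keeps the species label of
its majority contributor. Everything is a pure function of the seed.

What it does **not** emulate: chimeras, PCR-copy correlation between
errors, homopolymer-specific error profiles, conserved/variable site
structure within real 16S genes, and cross-species sequence similarity
below the enforced separation. Passing tests on these fixtures
demonstrate algorithmic correctness (completeness, exactness,
determinism) and the qualitative effect of the fastidious step, not
field-realistic quality values.

## Numerical and formatting choices

* Degenerate metric denominators: precision (and recall) with no
  co-clustered (co-labelled) pairs is 1.0; the adjusted Rand index with
  a zero denominator is 1.0. Metrics are computed over unique amplicons,
  unweighted; an abundance-weighted variant exists behind the `weights`
  argument.
* Statistics output, column 7: the radius — the maximum cumulative link
  distance from the seed along the member tree (column 6 is the maximum
  generation; they differ once links of distance > 1 occur).
* Uclust-like output: H records pair each member with its *parent* (the
  alignment the pipeline actually performed), percent identity
  100·(alen − d)/alen with alen = max of the two lengths; C records
  carry the member count.
* Grafting links in the internal-structures output carry a trailing `G`
  field; ordinary links have five fields.
* Abundance dialects: trailing `_N` (configurable separator) or
  `;size=N`; strict parsing is the default, `--append-abundance`
  defaults missing annotations to 1.

## Problem sizes used in the checks

The test suite verifies filter completeness on 20 generated communities
of 200–500 unique amplicons (lengths 150–300) for tau ∈ {1,2,3,4,6} and
k ∈ {1,2}; verification against full-DP references on 10⁴ random pairs
(edit) and 10³ short pairs (scoring mode, unbanded reference, itself
checked against literal alignment enumeration on tiny pairs); and
clustering equality with an unfiltered brute-force implementation of the
iterative strategy on 10 fixtures for t ∈ {1,2,3}, breaking on and off.
The acceptance script clusters a default-condition community (typically
5–7 thousand unique amplicons) in about a minute on one core.

## Known limitations

* Pure-Python DP kernels: throughput is adequate for communities of
  10⁴–10⁵ amplicons, not for multi-million-read studies.
* The relaxed k > 1 windows verify more candidates than the tight
  generalised multimatch bound would admit.
* Ambiguous bases are filtered out rather than matched (IUPAC-aware
  matching is out of scope).
* Pools are processed sequentially; no parallelism.
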