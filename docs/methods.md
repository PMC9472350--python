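# Methods

This note records the model implemented by `l1pattern`, its numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Probe design

Input is an aligned query set: ≥ 2 gapped sequences over `{A,C,G,T,-,N}`
of equal length, named ORF column ranges, and an element span. Per-column
conservation is the count of the modal base among A/C/G/T divided by the
member count; gaps and N count in the denominator and can never be modal.
This is deliberate: a probe must exist as a contiguous k-mer in most
members, so a column gapped in many members must score low regardless of
how well the remaining bases agree. The threshold comparison is inclusive
("at least 95%") with a 1e-9 float guard.

Conserved blocks are maximal runs of ≥ `min_block_len` (default 50)
columns at or above `min_column_similarity` (default 0.95). Candidates
are the column-wise modal-base consensus of *every* k-column window
(default k = 50) fully inside a block — enumerating every offset is the
superset of any sparser choice — restricted to windows fully inside one
ORF and not straddling a gap-majority column.

Refinement:

1. **ORF specificity** — a candidate is dropped when any of its exact
   occurrences in any ungapped member overlaps a different ORF. Exact
   matching is the strictest deterministic reading of "maps to".
2. **Background minimality** — exact hit counts (both strands) on a
   user-supplied decoy genome; all candidates tied at the minimum
   survive, since no tie rule is more defensible than another.
3. **Non-overlap** — greedy left-to-right selection by alignment column,
   which preserves 5'→3' coverage and is deterministic.

The layout is then measured on the members: each probe is located in each
ungapped member by best approximate occurrence with ≤ 2 edits (leftmost
on ties); members missing a probe are excluded from that probe's
averages, and a probe found in under half the members is dropped with a
warning. Offsets from the element start, offsets from the ORF1 start,
adjacent start-to-start distances and the tail length (last probe end to
element end) are arithmetic means rounded to the nearest base. The probe
count is whatever survives — sixteen (five ORF1 + eleven ORF2) in the
packaged synthetic fixture, mirroring the canonical human L1 instance,
but nothing in the code assumes that number.

## Seed mapping

A seed is a locus whose forward sequence matches the probe (plus strand)
or its reverse complement (minus strand) within Levenshtein distance δ.
Hit semantics are defined start-wise: `d(s)` is the minimum distance over
substrings starting at `s`; hits within `k − 1` bases of their
predecessor collapse to the best-scoring start (ties → leftmost); the
reported end uses the window length achieving `d(s)`, preferring lengths
closest to `k`, then shorter. N in the genome matches nothing.

The mapper is **anchored**: each probe is cut into `⌊k/12⌋`
non-overlapping 12-bp fragments, candidate starts are those within δ of
an exact fragment occurrence at the fragment's offset (found via a sorted
12-mer index of the genome), and candidates are verified with a Myers
bit-vector computation of `d(s)` (run on reversed sequences to obtain
start-wise distances). By the pigeonhole principle this is *exactly*
equivalent to an exhaustive scan whenever δ < ⌊k/12⌋, i.e. δ ≤ 3 for
50-mers — the regime the test-suite oracle checks exhaustively. For
larger δ only anchored loci are examined. This is a deliberate design
choice, not an approximation of convenience: at δ = 20 a 50-mer is
allowed 40% divergence, and an exhaustive scan then accepts roughly one
start per kilobase of *random* sequence per probe and strand (measured:
~8×10⁻⁴ collapsed seeds/bp), which makes chains of ≥ 9 ordered seeds
appear by chance in any genome-sized input. Anchoring keeps the false
seed rate near `4·(2δ+1)·4⁻¹²` ≈ 10⁻⁵/bp, the regime in which the
published default δ = 20 is meaningful for fast anchored mappers.

## Chaining

Seeds on one chromosome and strand chain when both position and probe
order increase strictly along the genome (probe order is reversed on the
minus strand) and every consecutive link satisfies
`|expected − observed| ≤ t`, where the expected gap between probes
`i < j` telescopes the average adjacent distances `d_i + … + d_{j−1}` and
the observed gap is start-to-start (matching how the offsets were
averaged). The per-link threshold stays `t` regardless of how many
probes a link skips — the simplest consistent generalization of the
adjacent-pair inequality; cumulative scaling would be an alternative and
is noted as such.

`chain_seeds` returns chains that are *subset-maximal*: no reported
chain's seed set is a proper subset of another valid chain's. The
implementation builds the DAG of valid links, discards transitively
reducible edges (if `u→w→v` is valid, any chain using `u→v` directly is
non-maximal), enumerates root-to-sink paths and filters residual subset
cases; the test suite checks exact agreement with brute-force subset
enumeration. Overlap resolution then greedily keeps chains by (seed
count desc, total gap deviation asc, leftmost start), forbidding shared
seeds and overlapping inferred spans on the same strand, so a seed
appears in at most one reported match.

Element bounds extrapolate from the terminal seeds using the probes'
average offsets and the average element length (mirrored on the minus
strand), clamped to the chromosome. This is one reasonable convention
among several; truth matching in the evaluator is overlap-based, so the
convention does not affect the reported counts.

## Evaluation and CNV

Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, all
zero when undefined so sweeps stay total. A prediction is a true positive
when it can be assigned one-to-one to a same-strand truth interval with
positive overlap (greedy by descending overlap); a reciprocal-overlap
fraction (e.g. 0.5) can tighten this but is off by default, and the
choice is visible in the API so users can audit it. The parameter sweep
shares the seed index per δ and the chain set per (δ, t) since `m` only
filters chains by length; the F1-argmax breaks ties toward smaller m,
then t, then δ. The published grid (2 ≤ m ≤ 16, 25 ≤ t ≤ 800,
5 ≤ δ ≤ 30) is a convention of that study, not a constraint: the sweep
accepts any structurally valid grid (t > 0, 0 ≤ δ < k, 2 ≤ m ≤ P).

CNVPG = (SPC − RPC)/RPC × 100 is exact internally and rounded to 5
decimals only at presentation, matching how published tables print it.

## Synthetic data

The generator defines the benchmark conditions:

* **Element model** — a 6 kb uniform-random consensus tiled as 5'UTR
  (908 bp), ORF1 (1017 bp), inter-ORF (63 bp), ORF2 (3828 bp), 3'UTR
  (184 bp), with sixteen 70-column conserved blocks (five in ORF1, eleven
  in ORF2). The gap before the penultimate ORF2 block is widened to
  ~570 bp so that the canonical 396-base internal deletion fits between
  two consecutive probe loci with margin. Genomic copies carry a poly(A)
  tail of 12–28 bases.
* **Member variation** — substitutions at 15% per base outside blocks,
  and inside blocks a per-column cap of ⌊5% · n⌋ deviating members, which
  *guarantees* the blocks pass a 95% conservation scan. The 15% outside
  rate is higher than real within-family divergence of intact L1s
  (~2–5%); it is chosen so the 0.95 threshold separates designed blocks
  from background columns at n = 20 members (at 5% divergence, ~74% of
  background columns would pass by chance and block boundaries would be
  meaningless). Small deletions (Poisson mean 8 events of 1–3 bp per
  member, outside blocks) appear as gap columns, keeping the returned
  alignment consistent without realignment; insertions are not generated.
* **Planted genomes** — i.i.d. uniform ACGT background with copies at
  non-overlapping positions ≥ 800 bp apart, strand Bernoulli(0.5).
  Integrity classes: intact, 5'-truncated (prefix of 800–4200 consensus
  bases removed), internal deletion (the 396-base span), and decayed
  (25% substitutions everywhere). Perturbation deletes whole recorded
  spans and/or inserts fresh intact copies into background at least
  800 bp from existing copies, with exact truth bookkeeping.

What passing these tests shows: the pipeline recovers planted layouts
exactly, responds linearly to copy-number changes (slope 1 across ±20
copies on a 50-copy chromosome), rejects uniform background at default
parameters, and reproduces the internal-deletion edge case (found while
m ≤ 14 at t = 50, lost for m > 14). What it does not show: performance on
real genomes, whose background is itself a graveyard of decayed element
fragments rather than uniform noise — precision there depends on the
decoy-based probe filtering and on the m/t trade-off, which is why the
sweep machinery is part of the package rather than a fixed constant.

## Problem sizes and determinism

Default benchmark sizes (query set n = 20, decoy 120 kb, 150 kb
background with 25–50 planted copies, perturbations of ±20 copies) were
chosen so every planted-copy experiment is exact and the full suite and
acceptance script run comfortably on one CPU. All generators take
explicit seeds and are bit-reproducible; detection is deterministic for
fixed inputs, with every tie-break (cluster representative, chain
ordering, overlap resolution, sweep argmax) specified leftmost-first.

## Known limitations

* Anchored mapping above δ = 3 reports only loci sharing an exact 12-mer
  with a probe; heavily mutated copies with no intact anchor in any probe
  are invisible (as with any anchored mapper).
* The untranslated regions contribute no probes by design, so element
  bounds at the UTRs are extrapolated averages, not measured ones.
* Poly(A) tails and target-site duplications are neither modeled in
  detection nor simulated beyond a plain adenine run.
* `match_predictions` is greedy, not an optimal bipartite assignment;
  for the near-disjoint intervals this tool emits the two coincide.
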