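"""Probe design: derive an ordered set of conserved k-mer probes from an
aligned query set.

The query set is a multiple sequence alignment of the element family to be
detected (for LINE-1: full-length, ORF-intact copies).  Probes are consensus
k-mers taken from alignment blocks whose columns are conserved in at least a
given fraction of the members, restricted to the ORF regions, and then
refined in three steps: (1) drop candidates that also match a different ORF
in any member, (2) keep only candidates with the fewest exact hits on a
background ("decoy") genome, (3) greedily keep a maximal set of
non-overlapping candidates left to right.  The surviving probes are stored
5'->3' together with their average offsets from the element start and the
average distances between consecutive probe starts -- the layout that the
seed chainer matches against.

Coordinates are 0-based half-open throughout; external TSV sidecars use
1-based inclusive columns.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
import numpy as np

from ._util import DNA, GAP, read_fasta, revcomp, write_fasta

__all__ = [
    "AlignedQuerySet",
    "ProbeDesignParams",
    "Probe",
    "ProbeSet",
    "Candidate",
    "column_conservation",
    "find_conserved_blocks",
    "extract_candidates",
    "refine_candidates",
    "compute_layout",
    "design_probes",
    "load_query_set",
]

_EPS = 1e-9  # guards float threshold comparisons ("at least 95%" is inclusive)


@dataclass(frozen=True)
class AlignedQuerySet:
    """A gapped multiple sequence alignment of the query element family.

    members
        ``(id, aligned sequence)`` pairs over the alphabet {A,C,G,T,-,N}.
    orf_ranges
        Named ORF regions as alignment-column ranges (0-based half-open).
    element_span
        Alignment-column range of the full element.
    """

    members: tuple[tuple[str, str], ...]
    orf_ranges: dict[str, tuple[int, int]]
    element_span: tuple[int, int]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("query set needs at least 2 members")
        lengths = {len(s) for _, s in self.members}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: members differ in length")
        ncol = lengths.pop()
        lo, hi = self.element_span
        if not (0 <= lo < hi <= ncol):
            raise ValueError("element_span outside alignment")
        spans = sorted(self.orf_ranges.values())
        for (a, b) in spans:
            if not (lo <= a < b <= hi):
                raise ValueError("ORF range outside element span")
        for (_, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("ORF ranges overlap")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_columns(self) -> int:
        return len(self.members[0][1])

    def ungapped(self, idx: int) -> str:
        return self.members[idx][1].replace(GAP, "")

    def column_to_position(self, idx: int) -> np.ndarray:
        """For one member, map each alignment column to its ungapped position.

        Gap columns map to the position of the next real base (i.e. the
        number of non-gap characters strictly before the column).
        """
        row = np.frombuffer(self.members[idx][1].encode("ascii"), dtype=np.uint8)
        nongap = row != ord(GAP)
        return np.cumsum(nongap) - nongap.astype(np.int64)

    def region_span_in_member(self, idx: int, region: str) -> tuple[int, int]:
        """Ungapped coordinates of a named region within one member."""
        a, b = self.orf_ranges[region]
        pos = self.column_to_position(idx)
        row = self.members[idx][1]
        end = pos[b - 1] + (1 if row[b - 1] != GAP else 0)
        return int(pos[a]), int(end)


@dataclass(frozen=True)
class ProbeDesignParams:
    k: int = 50
    min_column_similarity: float = 0.95
    min_block_len: int = 50

    def __post_init__(self):
        if not (0.0 < self.min_column_similarity <= 1.0):
            raise ValueError("min_column_similarity must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_block_len < self.k:
            raise ValueError("min_block_len must be >= k")


@dataclass(frozen=True)
class Probe:
    id: str
    sequence: str
    region: str
    avg_offset_element: int
    avg_offset_orf1: int


@dataclass(frozen=True)
class Candidate:
    """A pre-refinement consensus k-mer tagged with its alignment column."""

    sequence: str
    region: str
    column: int


@dataclass
class ProbeSet:
    """Ordered 5'->3' probes plus the average layout used for chaining.

    ``adjacent_distances[i]`` is the average distance in bases between the
    starts of probe ``i`` and probe ``i+1``; ``avg_tail_length`` is the
    average number of bases from the end of the last probe to the element
    end.
    """

    probes: list[Probe]
    adjacent_distances: list[int] = field(default_factory=list)
    avg_tail_length: int = 0

    def __post_init__(self):
        if not self.probes:
            raise ValueError("empty probe set")
        ks = {len(p.sequence) for p in self.probes}
        if len(ks) != 1:
            raise ValueError("probes must share one length")
        for p in self.probes:
            if any(c not in DNA for c in p.sequence):
                raise ValueError(f"probe {p.id} contains non-ACGT characters")
        offsets = [p.avg_offset_element for p in self.probes]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("probe offsets must be strictly increasing")
        if len(self.adjacent_distances) != len(self.probes) - 1:
            raise ValueError("adjacent_distances must have len(probes)-1 entries")
        if any(d <= 0 for d in self.adjacent_distances):
            raise ValueError("adjacent distances must be positive")

    @property
    def k(self) -> int:
        return len(self.probes[0].sequence)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def element_length(self) -> int:
        """Average element length implied by the layout."""
        return self.probes[-1].avg_offset_element + self.k + self.avg_tail_length

    # -- persistence: FASTA (sequences) + TSV sidecar (layout) ---------------

    def write(self, fasta_path: str | Path, meta_path: str | Path) -> None:
        write_fasta({p.id: p.sequence for p in self.probes}, fasta_path)
        with open(meta_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["probe_id", "region", "avg_offset_element", "avg_offset_orf1",
                 "adjacent_distance_to_next", "avg_tail_length"]
            )
            for i, p in enumerate(self.probes):
                nxt = self.adjacent_distances[i] if i < len(self.probes) - 1 else "."
                w.writerow([p.id, p.region, p.avg_offset_element,
                            p.avg_offset_orf1, nxt, self.avg_tail_length])

    @classmethod
    def read(cls, fasta_path: str | Path, meta_path: str | Path) -> "ProbeSet":
        seqs = read_fasta(fasta_path)
        probes, dists, tail = [], [], 0
        with open(meta_path) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        for row in rows:
            pid = row["probe_id"]
            if pid not in seqs:
                raise ValueError(f"probe {pid} missing from FASTA")
            probes.append(
                Probe(pid, seqs[pid], row["region"],
                      int(row["avg_offset_element"]), int(row["avg_offset_orf1"]))
            )
            if row["adjacent_distance_to_next"] != ".":
                dists.append(int(row["adjacent_distance_to_next"]))
            tail = int(row["avg_tail_length"])
        return cls(probes, dists, tail)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def column_conservation(alignment: AlignedQuerySet) -> np.ndarray:
    """Per-column conservation: modal A/C/G/T count over the member count.

    Gaps and N count in the denominator but can never be the modal base, so
    a column that is gapped in many members scores low even if the remaining
    bases agree.
    """
    rows = np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for _, s in alignment.members]
    )
    counts = np.stack([(rows == ord(b)).sum(axis=0) for b in DNA])
    return counts.max(axis=0) / alignment.n_members


def find_conserved_blocks(
    conservation: np.ndarray, params: ProbeDesignParams
) -> list[tuple[int, int]]:
    """Maximal runs of columns at or above the similarity threshold, at least
    ``min_block_len`` columns long.  Returned sorted and non-overlapping."""
    conservation = np.asarray(conservation, dtype=float)
    if conservation.size and (conservation.min() < 0 or conservation.max() > 1):
        raise ValueError("conservation values must lie in [0, 1]")
    ok = conservation >= params.min_column_similarity - _EPS
    blocks: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= params.min_block_len:
                blocks.append((start, i))
            start = None
    if start is not None and len(ok) - start >= params.min_block_len:
        blocks.append((start, len(ok)))
    return blocks


def _column_consensus(alignment: AlignedQuerySet) -> tuple[str, np.ndarray]:
    """Modal-base consensus per column (ties -> alphabetical) and a flag for
    gap-majority columns."""
    rows = np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for _, s in alignment.members]
    )
    counts = np.stack([(rows == ord(b)).sum(axis=0) for b in DNA])
    cons = np.array(list(DNA))[counts.argmax(axis=0)]
    gap_major = (rows == ord(GAP)).sum(axis=0) > alignment.n_members / 2
    return "".join(cons), gap_major


def extract_candidates(
    blocks: list[tuple[int, int]],
    alignment: AlignedQuerySet,
    params: ProbeDesignParams,
) -> list[Candidate]:
    """Consensus k-mers for every k-column window inside a conserved block.

    A window is kept only if it lies fully inside a single ORF region and
    does not straddle a gap-majority column.  Probes are restricted to ORFs
    because the untranslated ends of interspersed elements are too variable
    to anchor a layout.
    """
    consensus, gap_major = _column_consensus(alignment)
    k = params.k
    out: list[Candidate] = []
    for (a, b) in blocks:
        for start in range(a, b - k + 1):
            window = (start, start + k)
            region = next(
                (
                    name
                    for name, (ra, rb) in alignment.orf_ranges.items()
                    if ra <= window[0] and window[1] <= rb
                ),
                None,
            )
            if region is None:
                continue
            if gap_major[window[0] : window[1]].any():
                continue
            out.append(Candidate(consensus[window[0] : window[1]], region, start))
    return out


def _count_exact_hits(seq: str, haystacks: list[str]) -> int:
    """Exact (possibly overlapping) occurrences of seq or its reverse
    complement over a list of sequences."""
    total = 0
    for pattern in (seq, revcomp(seq)):
        for hay in haystacks:
            i = hay.find(pattern)
            while i != -1:
                total += 1
                i = hay.find(pattern, i + 1)
    return total


def refine_candidates(
    candidates: list[Candidate],
    query: AlignedQuerySet,
    decoy_genome: dict[str, str],
) -> ProbeSet:
    """Three-step refinement of candidate probes.

    1. ORF specificity: drop any candidate whose exact occurrences in some
       ungapped member overlap a different ORF than its own.
    2. Background minimality: keep only candidates whose exact hit count on
       the decoy genome is minimal (all ties survive).
    3. Non-overlap: greedy left-to-right selection of mutually
       non-overlapping candidates (by alignment column).

    Returns a ProbeSet with a provisional alignment-column layout; run
    :func:`compute_layout` to replace it with member-averaged offsets.
    """
    if not candidates:
        raise ValueError("no candidates to refine")
    k = len(candidates[0].sequence)

    members = [query.ungapped(i) for i in range(query.n_members)]
    region_spans = [
        {r: query.region_span_in_member(i, r) for r in query.orf_ranges}
        for i in range(query.n_members)
    ]

    def orf_specific(cand: Candidate) -> bool:
        for seq, spans in zip(members, region_spans):
            i = seq.find(cand.sequence)
            while i != -1:
                hit = (i, i + k)
                for region, (ra, rb) in spans.items():
                    if region != cand.region and hit[0] < rb and ra < hit[1]:
                        return False
                i = seq.find(cand.sequence, i + 1)
        return True

    step1 = [c for c in candidates if orf_specific(c)]
    if not step1:
        raise ValueError("no probes survive refinement")

    decoy_seqs = list(decoy_genome.values())
    hits = [_count_exact_hits(c.sequence, decoy_seqs) for c in step1]
    lowest = min(hits)
    step2 = [c for c, h in zip(step1, hits) if h == lowest]

    step3: list[Candidate] = []
    for cand in sorted(step2, key=lambda c: c.column):
        if not step3 or cand.column >= step3[-1].column + k:
            step3.append(cand)
    if not step3:
        raise ValueError("no probes survive refinement")

    col0 = query.element_span[0]
    probes = [
        Probe(f"probe_{i + 1:02d}", c.sequence, c.region, c.column - col0, 0)
        for i, c in enumerate(step3)
    ]
    dists = [b.avg_offset_element - a.avg_offset_element for a, b in zip(probes, probes[1:])]
    tail = max(0, (query.element_span[1] - col0) - (probes[-1].avg_offset_element + k))
    return ProbeSet(probes, dists, tail)


def _locate(probe: str, member: str, max_edits: int = 2) -> int | None:
    """Leftmost start of the best approximate occurrence (edit distance <=
    max_edits) of probe in member, or None."""
    res = edlib.align(probe, member, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    return min(start for start, _ in res["locations"])


def compute_layout(probeset: ProbeSet, query: AlignedQuerySet) -> ProbeSet:
    """Fill in member-averaged offsets, adjacent distances and tail length.

    Each probe is located in every ungapped member (edit distance <= 2,
    leftmost best hit); members missing a probe are excluded from that
    probe's averages, and a probe located in fewer than half the members is
    dropped with a warning.  Offsets and distances are arithmetic means
    rounded to the nearest base.
    """
    n = query.n_members
    members = [query.ungapped(i) for i in range(query.n_members)]
    col_lo, col_hi = query.element_span
    elem_bounds = []
    orf1 = min(query.orf_ranges, key=lambda r: query.orf_ranges[r][0])
    for i in range(n):
        pos = query.column_to_position(i)
        row = query.members[i][1]
        end = int(pos[col_hi - 1]) + (1 if row[col_hi - 1] != GAP else 0)
        elem_bounds.append((int(pos[col_lo]), end, int(pos[query.orf_ranges[orf1][0]])))

    located: list[tuple[Probe, list[int | None]]] = []
    for probe in probeset.probes:
        starts = [_locate(probe.sequence, m) for m in members]
        found = sum(s is not None for s in starts)
        if found < n / 2:
            warnings.warn(
                f"probe {probe.id} located in only {found}/{n} members; dropped",
                stacklevel=2,
            )
            continue
        located.append((probe, starts))
    if not located:
        raise ValueError("no probes could be located in the query members")

    k = probeset.k
    probes: list[Probe] = []
    for probe, starts in located:
        offs_elem = [s - eb[0] for s, eb in zip(starts, elem_bounds) if s is not None]
        offs_orf1 = [s - eb[2] for s, eb in zip(starts, elem_bounds) if s is not None]
        probes.append(
            replace(
                probe,
                avg_offset_element=round(float(np.mean(offs_elem))),
                avg_offset_orf1=round(float(np.mean(offs_orf1))),
            )
        )

    dists = []
    for (_, sa), (_, sb) in zip(located, located[1:]):
        gaps = [b - a for a, b in zip(sa, sb) if a is not None and b is not None]
        if not gaps:
            raise ValueError("no member contains two consecutive probes")
        dists.append(round(float(np.mean(gaps))))

    _, last_starts = located[-1]
    tails = [
        eb[1] - (s + k) for s, eb in zip(last_starts, elem_bounds) if s is not None
    ]
    tail = max(0, round(float(np.mean(tails))))
    return ProbeSet(probes, dists, tail)


def design_probes(
    query: AlignedQuerySet,
    decoy_genome: dict[str, str],
    params: ProbeDesignParams | None = None,
) -> ProbeSet:
    """Full probe design pipeline: conservation scan -> blocks -> candidate
    k-mers -> three-step refinement -> member-averaged layout."""
    params = params or ProbeDesignParams()
    cons = column_conservation(query)
    blocks = find_conserved_blocks(cons, params)
    cands = extract_candidates(blocks, query, params)
    if not cands:
        raise ValueError("no candidate probes found; alignment too variable?")
    provisional = refine_candidates(cands, query, decoy_genome)
    return compute_layout(provisional, query)


def load_query_set(
    alignment_fasta: str | Path, orf_tsv: str | Path
) -> AlignedQuerySet:
    """Load an aligned FASTA plus an ORF-range sidecar TSV.

    The TSV has columns ``region_name, start_col, end_col`` with 1-based
    inclusive alignment columns.  A row named ``element`` (case-insensitive)
    gives the element span; it defaults to the full alignment.
    """
    seqs = read_fasta(alignment_fasta)
    members = tuple((name, seq) for name, seq in seqs.items())
    orf_ranges: dict[str, tuple[int, int]] = {}
    span = None
    with open(orf_tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("region_name"):
                continue
            name, a, b = line.split("\t")
            rng = (int(a) - 1, int(b))
            if name.lower() == "element":
                span = rng
            else:
                orf_ranges[name] = rng
    if span is None:
        span = (0, len(members[0][1]))
    return AlignedQuerySet(members, orf_ranges, span)
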