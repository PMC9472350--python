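"""Approximate probe mapping: find seeds (approximate probe occurrences)
on both strands of a target genome.

The mapper is anchored, in the style of fast read mappers built for
structural-variation discovery: each probe is split into non-overlapping
anchor fragments of ``ANCHOR_W`` bases, candidate loci are the positions
where some fragment occurs *exactly* at its expected offset (within a band
of +/- delta to absorb indels), and candidates are then verified with a
Myers bit-vector edit-distance computation.  By the pigeonhole principle
this is fully sensitive -- identical to an exhaustive Levenshtein scan --
whenever ``delta < floor(k / ANCHOR_W)`` (delta <= 3 for 50-mers).  For
larger delta, loci with no exact anchor are not reported; this mirrors how
the probes behave in practice with anchored mappers and is what keeps large
edit distances usable at all (an exhaustive scan at delta = 20 accepts 40%
divergence and hits random sequence roughly every kilobase).

Hit semantics (shared with the brute-force oracle used in the tests):

* for a start position ``s``, ``d(s)`` is the minimum Levenshtein distance
  between the probe and any genome substring starting at ``s``;
* every examined ``s`` with ``d(s) <= delta`` is a hit;
* runs of hits whose starts are within ``k - 1`` of their predecessor are
  collapsed to the best-scoring start (ties -> leftmost);
* the reported end uses the window length achieving ``d(s)``, preferring
  lengths closest to ``k`` (ties -> shorter);
* N in the genome never matches anything.

Coordinates are 0-based half-open; minus-strand seeds are positions of the
probe's reverse complement on the forward sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import DNA, encode, revcomp
from .probe_design import ProbeSet

__all__ = ["DetectionParams", "Seed", "SeedIndex", "GenomeIndex", "map_probe", "map_probeset", "ANCHOR_W"]

ANCHOR_W = 12


@dataclass(frozen=True)
class DetectionParams:
    """Detection parameters.

    m
        Minimum number of seeds per pattern match.
    t
        Distance threshold (bases): a chain link is valid when the observed
        gap deviates from the probes' average gap by at most t.
    delta
        Maximum edit distance per probe hit.
    """

    m: int = 9
    t: int = 700
    delta: int = 20

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    def validate_for(self, probeset: ProbeSet) -> None:
        if self.m > len(probeset):
            raise ValueError(f"m={self.m} exceeds probe count {len(probeset)}")
        if self.delta >= probeset.k:
            raise ValueError("delta must be smaller than the probe length")


@dataclass(frozen=True, order=True)
class Seed:
    """An approximate probe occurrence on the genome."""

    chrom: str
    strand: str
    start: int
    end: int
    probe_index: int
    edit_distance: int


@dataclass
class SeedIndex:
    """Seeds grouped by (chrom, strand), each group sorted by start."""

    seeds: dict[tuple[str, str], list[Seed]]
    chrom_lengths: dict[str, int]

    def all_seeds(self) -> list[Seed]:
        return [s for group in self.seeds.values() for s in group]

    def __len__(self) -> int:
        return sum(len(v) for v in self.seeds.values())


class GenomeIndex:
    """Exact w-mer index over a genome (one sorted code array per chrom)."""

    def __init__(self, genome: dict[str, str], w: int = ANCHOR_W):
        self.w = w
        self.genome = genome
        self.codes: dict[str, np.ndarray] = {name: encode(seq) for name, seq in genome.items()}
        self._kmer_sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, codes in self.codes.items():
            n = len(codes)
            if n < w:
                self._kmer_sorted[name] = (np.empty(0, np.int64), np.empty(0, np.int64))
                continue
            valid = codes < 4
            # rolling w-mer codes in base 4; windows containing N are excluded
            kcodes = np.zeros(n - w + 1, dtype=np.int64)
            ok = np.ones(n - w + 1, dtype=bool)
            c = codes.astype(np.int64)
            for j in range(w):
                kcodes = kcodes * 4 + c[j : n - w + 1 + j]
                ok &= valid[j : n - w + 1 + j]
            positions = np.flatnonzero(ok)
            kc = kcodes[positions]
            order = np.argsort(kc, kind="stable")
            self._kmer_sorted[name] = (kc[order], positions[order])

    def find_exact(self, chrom: str, fragment_codes: np.ndarray) -> np.ndarray:
        """Start positions of exact occurrences of a w-mer fragment."""
        code = 0
        for c in fragment_codes:
            code = code * 4 + int(c)
        kc, pos = self._kmer_sorted[chrom]
        lo = np.searchsorted(kc, code, side="left")
        hi = np.searchsorted(kc, code, side="right")
        return np.sort(pos[lo:hi])


# ---------------------------------------------------------------------------
# Myers bit-vector verification (pattern length <= 63)
# ---------------------------------------------------------------------------

def _myers_end_distances(pattern: str, text_codes: np.ndarray) -> list[int]:
    """Best edit distance of pattern against a window ending at each text
    position (semi-global: free gaps in the text before the window)."""
    m = len(pattern)
    if m > 63:
        raise ValueError("pattern too long for bit-vector verification")
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    peq = [0] * 5
    for i, ch in enumerate(pattern):
        peq[DNA.index(ch)] |= 1 << i
    pv, mv, score = mask, 0, m
    out = []
    for code in text_codes:
        eq = peq[code]
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | (~(xh | pv) & mask)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        ph = (ph << 1) & mask
        mh = (mh << 1) & mask
        pv = mh | (~(xv | ph) & mask)
        mv = ph & xv
        out.append(score)
    return out


def _start_distances(pattern: str, codes: np.ndarray, lo: int, hi: int) -> list[int]:
    """d(s) for every start s in [lo, hi): min edit distance of pattern vs a
    genome substring starting at s.  Computed by running the end-distance
    recurrence on the reversed segment."""
    k = len(pattern)
    delta_room = k  # any alignment within distance < k spans < 2k bases
    seg_end = min(len(codes), hi - 1 + k + delta_room)
    seg = codes[lo:seg_end][::-1]
    rev_end = _myers_end_distances(pattern[::-1], seg)
    # end position j in reversed segment corresponds to forward start lo + (len(seg) - 1 - j)
    n = len(seg)
    return [rev_end[n - 1 - (s - lo)] for s in range(lo, hi)]


def _prefix_distances(pattern: str, window_codes: np.ndarray) -> list[int]:
    """lev(pattern, window[:L]) for L = 0..len(window) (classic DP)."""
    m = len(pattern)
    pcodes = [DNA.index(c) for c in pattern]
    col = list(range(m + 1))
    out = [m]
    for j, wc in enumerate(window_codes, start=1):
        new = [j]
        for i in range(1, m + 1):
            new.append(
                min(
                    col[i - 1] + (0 if pcodes[i - 1] == wc else 1),
                    col[i] + 1,
                    new[i - 1] + 1,
                )
            )
        col = new
        out.append(col[m])
    return out


def _best_end(pattern: str, codes: np.ndarray, start: int, delta: int) -> int:
    """Window length achieving d(start), preferring |L - k| small, then
    shorter; returns the end coordinate."""
    k = len(pattern)
    lo_len = max(0, k - delta)
    hi_len = min(k + delta, len(codes) - start)
    pref = _prefix_distances(pattern, codes[start : start + hi_len])
    best = None
    for length in range(lo_len, hi_len + 1):
        d = pref[length]
        key = (d, abs(length - k), length)
        if best is None or key < best[0]:
            best = (key, length)
    return start + best[1]


def _candidate_runs(
    index: GenomeIndex, chrom: str, pattern: str, delta: int
) -> list[tuple[int, int]]:
    """Merged [lo, hi) ranges of start positions to examine: within delta of
    an exact anchor-fragment hit at the fragment's probe offset."""
    w = index.w
    k = len(pattern)
    n = len(index.codes[chrom])
    if n == 0:
        return []
    pat_codes = encode(pattern)
    starts: list[tuple[int, int]] = []
    for frag_off in range(0, k - w + 1, w):
        frag = pat_codes[frag_off : frag_off + w]
        for pos in index.find_exact(chrom, frag):
            s_lo = max(0, int(pos) - frag_off - delta)
            s_hi = min(n - 1, int(pos) - frag_off + delta)
            if s_hi >= s_lo:
                starts.append((s_lo, s_hi + 1))
    if not starts:
        return []
    starts.sort()
    merged = [list(starts[0])]
    for lo, hi in starts[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _map_pattern_one_strand(
    index: GenomeIndex, chrom: str, strand: str, pattern: str,
    probe_index: int, delta: int,
) -> list[Seed]:
    codes = index.codes[chrom]
    k = len(pattern)
    hits: list[tuple[int, int]] = []  # (start, distance)
    for lo, hi in _candidate_runs(index, chrom, pattern, delta):
        dists = _start_distances(pattern, codes, lo, hi)
        hits.extend((lo + i, d) for i, d in enumerate(dists) if d <= delta)
    if not hits:
        return []
    hits.sort()
    seeds: list[Seed] = []
    cluster: list[tuple[int, int]] = [hits[0]]
    for h in hits[1:]:
        if h[0] - cluster[-1][0] < k:
            cluster.append(h)
        else:
            seeds.append(_emit(pattern, codes, cluster, chrom, strand, probe_index, delta))
            cluster = [h]
    seeds.append(_emit(pattern, codes, cluster, chrom, strand, probe_index, delta))
    return seeds


def _emit(
    pattern: str, codes: np.ndarray, cluster: list[tuple[int, int]],
    chrom: str, strand: str, probe_index: int, delta: int,
) -> Seed:
    best_d = min(d for _, d in cluster)
    start = min(s for s, d in cluster if d == best_d)
    end = _best_end(pattern, codes, start, delta)
    return Seed(chrom, strand, start, end, probe_index, best_d)


def map_probe(
    genome: dict[str, str] | GenomeIndex,
    probe: str,
    delta: int,
    probe_index: int = 0,
) -> list[Seed]:
    """All seeds for one probe, both strands, sorted by (chrom, strand, start).

    A minus-strand seed is a locus whose forward sequence approximately
    matches the reverse complement of the probe.
    """
    if any(c not in DNA for c in probe.upper()):
        raise ValueError("probe contains non-ACGT characters")
    probe = probe.upper()
    if delta >= len(probe):
        raise ValueError("delta must be smaller than the probe length")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    seeds: list[Seed] = []
    for chrom in index.codes:
        for strand, pattern in (("+", probe), ("-", revcomp(probe))):
            seeds.extend(
                _map_pattern_one_strand(index, chrom, strand, pattern, probe_index, delta)
            )
    seeds.sort(key=lambda s: (s.chrom, s.strand, s.start, s.probe_index))
    return seeds


def map_probeset(
    genome: dict[str, str] | GenomeIndex,
    probeset: ProbeSet,
    params: DetectionParams,
) -> SeedIndex:
    """Union of :func:`map_probe` over all probes, grouped by chrom/strand."""
    params.validate_for(probeset)
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    grouped: dict[tuple[str, str], list[Seed]] = {}
    for i, probe in enumerate(probeset.probes):
        for seed in map_probe(index, probe.sequence, params.delta, probe_index=i):
            grouped.setdefault((seed.chrom, seed.strand), []).append(seed)
    for group in grouped.values():
        group.sort(key=lambda s: (s.start, s.probe_index))
    lengths = {name: len(seq) for name, seq in index.genome.items()}
    return SeedIndex(grouped, lengths)
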