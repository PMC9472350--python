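"""Seed chaining: assemble seeds into pattern matches.

A pattern match is a chain of at least ``m`` seeds, on one chromosome and
strand, whose probe order follows the element's 5'->3' layout and whose
start-to-start gaps agree with the probes' average gaps within the
threshold ``t``.  For seeds of probes ``i < j`` the expected gap is the
telescoped sum of the average adjacent distances ``d_i + ... + d_{j-1}``,
so a chain may skip probes lost to truncation or internal deletion and the
per-link tolerance stays ``t``.  On the minus strand the element is reverse
complemented, so probe indices decrease along the forward coordinate while
the same expected gaps apply.

Chains are maximal: a chain is reported only if its seed set is not a
proper subset of another valid chain's.  Overlapping survivors are reduced
to a non-conflicting set greedily (most seeds, then smallest total gap
deviation, then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .probe_design import ProbeSet
from .seed_mapping import DetectionParams, Seed, SeedIndex, map_probeset

__all__ = [
    "PatternMatch",
    "expected_gap",
    "chain_seeds",
    "resolve_overlaps",
    "infer_element_bounds",
    "detect",
]


@dataclass(frozen=True)
class PatternMatch:
    chrom: str
    strand: str
    seeds: tuple[Seed, ...]
    observed_gaps: tuple[int, ...]
    element_start: int
    element_end: int
    total_deviation: int

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def probe_indices(self) -> tuple[int, ...]:
        return tuple(s.probe_index for s in self.seeds)


def expected_gap(probeset: ProbeSet, i: int, j: int) -> int:
    """Average distance between the starts of probes i and j (i < j):
    the telescoped sum of the adjacent distances."""
    if i >= j:
        raise ValueError("expected_gap requires i < j")
    if i < 0 or j >= len(probeset):
        raise ValueError("probe index out of range")
    return sum(probeset.adjacent_distances[i:j])


def _link_ok(left: Seed, right: Seed, probeset: ProbeSet, t: int, strand: str) -> bool:
    """Is (left -> right, by position) a valid chain link?"""
    if right.start <= left.start:
        return False
    if strand == "+":
        if right.probe_index <= left.probe_index:
            return False
        exp = expected_gap(probeset, left.probe_index, right.probe_index)
    else:
        if right.probe_index >= left.probe_index:
            return False
        exp = expected_gap(probeset, right.probe_index, left.probe_index)
    return abs(exp - (right.start - left.start)) <= t


def _chain_group(
    seeds: list[Seed], probeset: ProbeSet, strand: str, t: int
) -> list[list[int]]:
    """All maximal valid chains in one (chrom, strand) group, as index lists.

    Builds the DAG of valid links, discards transitively-reducible edges (a
    link u->v is useless if some w can be inserted between them, since any
    chain using it is then non-maximal), enumerates root-to-sink paths and
    finally removes chains whose seed set is a proper subset of another's.
    """
    n = len(seeds)
    max_reach = expected_gap(probeset, 0, len(probeset) - 1) + t if len(probeset) > 1 else t
    succ: list[list[int]] = [[] for _ in range(n)]
    succ_sets: list[set[int]] = [set() for _ in range(n)]
    has_pred = [False] * n
    for u in range(n):
        su = seeds[u]
        for v in range(u + 1, n):
            sv = seeds[v]
            if sv.start - su.start > max_reach:
                break
            if _link_ok(su, sv, probeset, t, strand):
                succ[u].append(v)
                succ_sets[u].add(v)
                has_pred[v] = True

    reduced: list[list[int]] = [[] for _ in range(n)]
    for u in range(n):
        for v in succ[u]:
            if not any(v in succ_sets[w] for w in succ[u] if w != v):
                reduced[u].append(v)

    chains: list[list[int]] = []
    for root in range(n):
        if has_pred[root]:
            continue
        stack = [(root, [root])]
        while stack:
            node, path = stack.pop()
            if not reduced[node]:
                if len(path) >= 2:
                    chains.append(path)
                continue
            for v in reduced[node]:
                stack.append((v, path + [v]))

    sets = [frozenset(c) for c in chains]
    keep = []
    for i, c in enumerate(chains):
        if not any(j != i and sets[i] < sets[j] for j in range(len(chains))):
            keep.append(c)
    return keep


def _chain_to_match(
    idx_chain: list[int], seeds: list[Seed], probeset: ProbeSet, strand: str
) -> PatternMatch:
    chain = [seeds[i] for i in idx_chain]
    gaps = tuple(b.start - a.start for a, b in zip(chain, chain[1:]))
    dev = 0
    for a, b, g in zip(chain, chain[1:], gaps):
        if strand == "+":
            dev += abs(expected_gap(probeset, a.probe_index, b.probe_index) - g)
        else:
            dev += abs(expected_gap(probeset, b.probe_index, a.probe_index) - g)
    return PatternMatch(
        chrom=chain[0].chrom,
        strand=strand,
        seeds=tuple(chain),
        observed_gaps=gaps,
        element_start=chain[0].start,
        element_end=chain[-1].end,
        total_deviation=dev,
    )


def chain_seeds(
    seed_index: SeedIndex, probeset: ProbeSet, params: DetectionParams
) -> list[PatternMatch]:
    """All maximal chains of at least ``params.m`` seeds.

    Element bounds on the returned matches are the raw seed spans; use
    :func:`infer_element_bounds` to extrapolate to full element bounds.
    """
    out: list[PatternMatch] = []
    for (chrom, strand), seeds in sorted(seed_index.seeds.items()):
        for idx_chain in _chain_group(seeds, probeset, strand, params.t):
            if len(idx_chain) >= params.m:
                out.append(_chain_to_match(idx_chain, seeds, probeset, strand))
    out.sort(key=lambda m: (m.chrom, m.strand, m.element_start))
    return out


def resolve_overlaps(chains: list[PatternMatch]) -> list[PatternMatch]:
    """Reduce overlapping chains to a non-conflicting set.

    Two chains conflict when they share a seed or their element spans
    overlap on the same chromosome and strand.  Survivors are picked
    greedily by (n_seeds desc, total_deviation asc, element_start asc).
    """
    ranked = sorted(
        chains,
        key=lambda c: (-c.n_seeds, c.total_deviation, c.element_start, c.chrom, c.strand),
    )
    kept: list[PatternMatch] = []
    used_seeds: set[Seed] = set()
    for cand in ranked:
        if any(s in used_seeds for s in cand.seeds):
            continue
        clash = any(
            k.chrom == cand.chrom
            and k.strand == cand.strand
            and cand.element_start < k.element_end
            and k.element_start < cand.element_end
            for k in kept
        )
        if clash:
            continue
        kept.append(cand)
        used_seeds.update(cand.seeds)
    kept.sort(key=lambda m: (m.chrom, m.element_start, m.strand))
    return kept


def infer_element_bounds(
    match: PatternMatch, probeset: ProbeSet, chrom_length: int | None = None
) -> tuple[int, int]:
    """Extrapolate full element bounds from the terminal seeds' probe
    offsets and the average element length, clamped to the chromosome."""
    if not match.seeds:
        raise ValueError("empty match")
    length = probeset.element_length
    k = probeset.k
    first, last = match.seeds[0], match.seeds[-1]
    if match.strand == "+":
        start = first.start - probeset.probes[first.probe_index].avg_offset_element
        end = last.start + (length - probeset.probes[last.probe_index].avg_offset_element)
    else:
        # reverse complement: probe p starts at element_start + length - offset_p - k
        off_first = probeset.probes[first.probe_index].avg_offset_element
        off_last = probeset.probes[last.probe_index].avg_offset_element
        start = first.start - (length - off_first - k)
        end = last.end + off_last
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        end = start + 1
    return int(start), int(end)


def detect(
    genome: dict[str, str],
    probeset: ProbeSet,
    params: DetectionParams | None = None,
) -> list[PatternMatch]:
    """Full detection: map probes, chain seeds, extrapolate element bounds
    and resolve overlaps.  Deterministic for fixed inputs."""
    params = params or DetectionParams()
    params.validate_for(probeset)
    seed_index = map_probeset(genome, probeset, params)
    chains = chain_seeds(seed_index, probeset, params)
    bounded = []
    for chain in chains:
        start, end = infer_element_bounds(
            chain, probeset, seed_index.chrom_lengths.get(chain.chrom)
        )
        bounded.append(replace(chain, element_start=start, element_end=end))
    return resolve_overlaps(bounded)
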