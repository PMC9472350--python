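"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: the mapping oracle
scans every start position with edlib alignments, and the chaining oracle
enumerates every seed subset.  Both implement the same documented hit and
chain semantics as the package, from first principles.
"""

from itertools import combinations

import edlib

from l1pattern import revcomp
from l1pattern.pattern_chaining import expected_gap
from l1pattern.seed_mapping import Seed


def oracle_map(genome: dict[str, str], probe: str, delta: int) -> list[Seed]:
    """Exhaustive sliding-window mapping oracle.

    For every start, the best edit distance over window lengths in
    [k - delta, k + delta] is taken (via an edlib prefix alignment); hits
    within k-1 of their predecessor are collapsed to the best-scoring
    (ties: leftmost) start, and the end uses the window length closest to
    k among the minimizers (ties: shorter).
    """
    k = len(probe)
    out: list[Seed] = []
    for chrom, seq in genome.items():
        n = len(seq)
        for strand, pat in (("+", probe), ("-", revcomp(probe))):
            hits = []
            for s in range(n):
                win = seq[s : s + k + delta]
                d = edlib.align(pat, win, mode="SHW")["editDistance"]
                if 0 <= d <= delta:
                    hits.append((s, d))
            clusters: list[list[tuple[int, int]]] = []
            for h in hits:
                if clusters and h[0] - clusters[-1][-1][0] < k:
                    clusters[-1].append(h)
                else:
                    clusters.append([h])
            for cl in clusters:
                best_d = min(d for _, d in cl)
                s = min(x for x, d in cl if d == best_d)
                best = None
                for length in range(max(0, k - delta), min(k + delta, n - s) + 1):
                    d = edlib.align(pat, seq[s : s + length], mode="NW")["editDistance"]
                    key = (d, abs(length - k), length)
                    if best is None or key < best[0]:
                        best = (key, length)
                out.append(Seed(chrom, strand, s, s + best[1], 0, best_d))
    out.sort(key=lambda x: (x.chrom, x.strand, x.start, x.probe_index))
    return out


def oracle_chains(seeds_by_group, probeset, t: int, m: int):
    """All subset-maximal valid chains by exhaustive subset enumeration.

    Returns a sorted list of (chrom, strand, ((start, probe_index), ...))
    tuples for chains of at least m seeds.
    """
    out = []
    for (chrom, strand), seeds in seeds_by_group.items():
        valid: list[frozenset[int]] = []
        for r in range(2, len(seeds) + 1):
            for combo in combinations(range(len(seeds)), r):
                chain = sorted((seeds[i] for i in combo), key=lambda s: s.start)
                ok = True
                for a, b in zip(chain, chain[1:]):
                    if b.start <= a.start:
                        ok = False
                        break
                    if strand == "+":
                        if b.probe_index <= a.probe_index:
                            ok = False
                            break
                        exp = expected_gap(probeset, a.probe_index, b.probe_index)
                    else:
                        if b.probe_index >= a.probe_index:
                            ok = False
                            break
                        exp = expected_gap(probeset, b.probe_index, a.probe_index)
                    if abs(exp - (b.start - a.start)) > t:
                        ok = False
                        break
                if ok:
                    valid.append(frozenset(combo))
        maximal = [c for c in valid if not any(c < o for o in valid)]
        for c in maximal:
            if len(c) >= m:
                chain = sorted((seeds[i] for i in c), key=lambda s: s.start)
                out.append((chrom, strand, tuple((s.start, s.probe_index) for s in chain)))
    return sorted(out)
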