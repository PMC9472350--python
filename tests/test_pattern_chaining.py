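"""Seed chaining: link tests, maximal-chain extraction, overlap
resolution, element-bound inference and end-to-end detection."""

import numpy as np
import pytest

from l1pattern import (
    DetectionParams,
    chain_seeds,
    detect,
    evaluate_matches,
    expected_gap,
    infer_element_bounds,
    plant_elements,
    random_background,
    resolve_overlaps,
    revcomp,
    truth_to_intervals,
)
from l1pattern.pattern_chaining import PatternMatch
from l1pattern.probe_design import Probe, ProbeSet
from l1pattern.seed_mapping import Seed, SeedIndex

from oracles import oracle_chains


def _probeset(offsets, k=50):
    probes = [Probe(f"p{i}", "A" * k, "ORF1", off, 0) for i, off in enumerate(offsets)]
    dists = [b - a for a, b in zip(offsets, offsets[1:])]
    return ProbeSet(probes, dists, 100)


def _index(seeds, chrom_len=100_000):
    groups = {}
    for s in seeds:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    for g in groups.values():
        g.sort(key=lambda s: (s.start, s.probe_index))
    return SeedIndex(groups, {"c": chrom_len})


class TestExpectedGap:
    def test_adjacent_is_the_stored_distance(self):
        ps = _probeset([0, 500, 800])
        assert expected_gap(ps, 0, 1) == 500
        assert expected_gap(ps, 1, 2) == 300

    def test_telescoping_sum(self):
        ps = _probeset([0, 500, 800])
        assert expected_gap(ps, 0, 2) == 800

    def test_requires_increasing_indices(self):
        ps = _probeset([0, 500])
        with pytest.raises(ValueError):
            expected_gap(ps, 1, 1)
        with pytest.raises(ValueError):
            expected_gap(ps, 1, 0)


class TestChainSeeds:
    def test_three_seed_chain_within_threshold(self):
        ps = _probeset([0, 500, 800])
        seeds = [
            Seed("c", "+", 1000, 1050, 0, 0),
            Seed("c", "+", 1520, 1570, 1, 0),  # gap 520, expected 500
            Seed("c", "+", 1810, 1860, 2, 0),  # gap 290, expected 300
        ]
        chains = chain_seeds(_index(seeds), ps, DetectionParams(m=3, t=50, delta=3))
        assert len(chains) == 1
        assert chains[0].observed_gaps == (520, 290)
        assert chains[0].total_deviation == 30

    def test_broken_link_splits_and_short_chain_dropped(self):
        ps = _probeset([0, 500, 800])
        seeds = [
            Seed("c", "+", 1000, 1050, 0, 0),
            Seed("c", "+", 1600, 1650, 1, 0),  # gap 600: |100| > t
            Seed("c", "+", 1890, 1940, 2, 0),
        ]
        chains = chain_seeds(_index(seeds), ps, DetectionParams(m=3, t=50, delta=3))
        assert chains == []

    def test_minus_strand_uses_reversed_probe_order(self):
        ps = _probeset([0, 500, 800])
        seeds = [
            Seed("c", "-", 1000, 1050, 2, 0),
            Seed("c", "-", 1300, 1350, 1, 0),
            Seed("c", "-", 1800, 1850, 0, 0),
        ]
        chains = chain_seeds(_index(seeds), ps, DetectionParams(m=3, t=10, delta=3))
        assert len(chains) == 1
        assert chains[0].probe_indices == (2, 1, 0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(77)
        for trial in range(40):
            n_probes = int(rng.integers(4, 9))
            offsets = np.sort(rng.choice(np.arange(100, 6000), n_probes, replace=False))
            ps = _probeset([int(x) for x in offsets])
            n_seeds = int(rng.integers(2, 13))
            starts = rng.choice(np.arange(0, 5000), n_seeds, replace=False)
            seeds = [
                Seed("c", str(rng.choice(["+", "-"])), int(s), int(s) + 50,
                     int(rng.integers(0, n_probes)), int(rng.integers(0, 4)))
                for s in starts
            ]
            t = int(rng.choice([50, 200, 700]))
            m = int(rng.integers(2, 5))
            idx = _index(seeds)
            got = sorted(
                (c.chrom, c.strand, tuple((s.start, s.probe_index) for s in c.seeds))
                for c in chain_seeds(idx, ps, DetectionParams(m=m, t=t, delta=3))
            )
            assert got == oracle_chains(idx.seeds, ps, t, m)

    def test_chains_at_lower_t_contained_in_chains_at_higher_t(self, model, probeset):
        from l1pattern import map_probeset

        genome, _ = plant_elements(60_000, model, 8, seed=19)
        idx = map_probeset(genome, probeset, DetectionParams(delta=20))
        low = chain_seeds(idx, probeset, DetectionParams(m=2, t=100, delta=20))
        high = chain_seeds(idx, probeset, DetectionParams(m=2, t=400, delta=20))
        high_sets = [set(c.seeds) for c in high]
        for c in low:
            assert any(set(c.seeds) <= h for h in high_sets)


class TestResolveOverlaps:
    def _match(self, start, end, seeds, dev, strand="+"):
        return PatternMatch("c", strand, tuple(seeds), (), start, end, dev)

    def _seed(self, start, pi):
        return Seed("c", "+", start, start + 50, pi, 0)

    def test_disjoint_chains_both_kept(self):
        a = self._match(0, 100, [self._seed(0, 0), self._seed(60, 1)], 5)
        b = self._match(500, 600, [self._seed(500, 0), self._seed(560, 1)], 5)
        assert len(resolve_overlaps([a, b])) == 2

    def test_more_seeds_wins(self):
        shared = [self._seed(i * 60, i) for i in range(10)]
        a = self._match(0, 700, shared, 5)
        b = self._match(0, 700, shared[:9], 1)
        kept = resolve_overlaps([a, b])
        assert kept == [a]

    def test_deviation_breaks_seed_count_ties(self):
        a = self._match(0, 700, [self._seed(i * 60, i) for i in range(5)], 40)
        b = self._match(0, 700, [self._seed(i * 60 + 5, i) for i in range(5)], 12)
        kept = resolve_overlaps([a, b])
        assert kept == [b]


class TestInferBounds:
    def test_plus_strand_subtracts_probe_offset(self):
        ps = _probeset([908, 1500])
        match = PatternMatch(
            "c", "+", (Seed("c", "+", 10000, 10050, 0, 0), Seed("c", "+", 10592, 10642, 1, 0)),
            (592,), 10000, 10642, 0,
        )
        start, end = infer_element_bounds(match, ps)
        assert start == 10000 - 908
        assert end == 10592 + (ps.element_length - 1500)

    def test_clamped_to_chromosome(self):
        ps = _probeset([908, 1500])
        match = PatternMatch(
            "c", "+", (Seed("c", "+", 100, 150, 0, 0), Seed("c", "+", 692, 742, 1, 0)),
            (592,), 100, 742, 0,
        )
        start, end = infer_element_bounds(match, ps, chrom_length=800)
        assert start == 0
        assert end == 800

    def test_empty_match_rejected(self):
        ps = _probeset([0, 500])
        bad = PatternMatch("c", "+", (), (), 0, 0, 0)
        with pytest.raises(ValueError):
            infer_element_bounds(bad, ps)


class TestDetect:
    def test_background_only_gives_no_matches(self, probeset):
        genome = random_background(80_000, seed=3)
        assert detect(genome, probeset) == []

    def test_all_planted_intact_copies_found(self, probeset, planted25):
        genome, truth = planted25
        matches = detect(genome, probeset)
        assert len(matches) == 25
        result = evaluate_matches(matches, truth_to_intervals(truth))
        assert result.precision == 1.0 and result.recall == 1.0

    def test_inferred_bounds_near_truth(self, probeset, model):
        genome, truth = plant_elements(30_000, model, 3, seed=23)
        matches = detect(genome, probeset)
        assert len(matches) == 3
        for m, t in zip(matches, truth):
            assert abs(m.element_start - t.start) <= DetectionParams().t
            assert abs(m.element_end - t.end) <= DetectionParams().t
            assert m.strand == t.strand

    def test_match_count_non_increasing_in_m(self, probeset, planted_mixed):
        genome, _ = planted_mixed
        counts = [
            len(detect(genome, probeset, DetectionParams(m=m)))
            for m in (3, 6, 9, 12, 14, 16)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strand_mirror_symmetry(self, probeset, model):
        genome, _ = plant_elements(40_000, model, 5, seed=17)
        n = len(genome["chr1"])
        mirrored = detect({"chr1": revcomp(genome["chr1"])}, probeset)
        forward = detect(genome, probeset)
        flip = {"+": "-", "-": "+"}
        assert sorted(
            (n - m.element_end, n - m.element_start, flip[m.strand]) for m in mirrored
        ) == sorted((m.element_start, m.element_end, m.strand) for m in forward)

    def test_seed_appears_in_only_one_match(self, probeset, planted_mixed):
        genome, _ = planted_mixed
        matches = detect(genome, probeset, DetectionParams(m=5))
        seen = set()
        for m in matches:
            for s in m.seeds:
                assert s not in seen
                seen.add(s)
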