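"""Probe design: conservation scan, block finding, candidate extraction,
three-step refinement and layout averaging."""

import numpy as np
import pytest

from l1pattern.probe_design import (
    AlignedQuerySet,
    Candidate,
    ProbeDesignParams,
    ProbeSet,
    Probe,
    column_conservation,
    compute_layout,
    extract_candidates,
    find_conserved_blocks,
    refine_candidates,
)


def _aqs(rows, orf_ranges=None, span=None):
    members = tuple((f"m{i}", r) for i, r in enumerate(rows))
    ncol = len(rows[0])
    return AlignedQuerySet(
        members,
        orf_ranges or {"ORF1": (0, ncol)},
        span or (0, ncol),
    )


class TestColumnConservation:
    def test_unanimous_column_scores_one(self):
        aq = _aqs(["A" * 4] * 10)
        assert np.allclose(column_conservation(aq), 1.0)

    def test_gap_counts_in_denominator(self):
        rows = ["C"] * 19 + ["-"]
        aq = _aqs([r + "C" for r in rows])  # 2 columns to satisfy span checks
        cons = column_conservation(aq)
        assert cons[0] == pytest.approx(19 / 20)
        assert cons[1] == 1.0

    def test_matches_per_column_tally_oracle(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT-N"), size=40)) for _ in range(4)]
        aq = _aqs(rows)
        cons = column_conservation(aq)
        for j in range(40):
            col = [r[j] for r in rows]
            expected = max(col.count(b) for b in "ACGT") / 4
            assert cons[j] == pytest.approx(expected)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            _aqs(["ACGT", "ACG"])

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            _aqs(["ACGT"])


class TestFindConservedBlocks:
    def test_single_full_block(self):
        cons = np.ones(120)
        assert find_conserved_blocks(cons, ProbeDesignParams()) == [(0, 120)]

    def test_run_below_min_length_dropped(self):
        cons = np.concatenate([[0.5], np.ones(49), [0.5]])
        assert find_conserved_blocks(cons, ProbeDesignParams()) == []

    def test_threshold_is_inclusive(self):
        cons = np.full(60, 19 / 20)
        blocks = find_conserved_blocks(cons, ProbeDesignParams(min_column_similarity=0.95))
        assert blocks == [(0, 60)]

    def test_blocks_sorted_disjoint(self):
        cons = np.concatenate([np.ones(60), [0.1], np.ones(70), [0.1], np.ones(30)])
        blocks = find_conserved_blocks(cons, ProbeDesignParams())
        assert blocks == [(0, 60), (61, 131)]

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            find_conserved_blocks(np.array([0.5, 1.5]), ProbeDesignParams())


class TestExtractCandidates:
    def _query(self, ncol=300, seed=0):
        rng = np.random.default_rng(seed)
        row = "".join(rng.choice(list("ACGT"), size=ncol))
        return _aqs([row, row], orf_ranges={"ORF1": (0, 150), "ORF2": (150, ncol)})

    def test_window_counts(self):
        aq = self._query()
        params = ProbeDesignParams()
        assert len(extract_candidates([(0, 50)], aq, params)) == 1
        assert len(extract_candidates([(0, 60)], aq, params)) == 11

    def test_block_straddling_region_boundary_restricted(self):
        aq = self._query()
        # block spans the ORF1/ORF2 boundary at column 150
        cands = extract_candidates([(90, 210)], aq, ProbeDesignParams())
        assert all(c.column + 50 <= 150 or c.column >= 150 for c in cands)
        assert {c.region for c in cands} == {"ORF1", "ORF2"}

    def test_short_block_contributes_nothing(self):
        aq = self._query()
        assert extract_candidates([(0, 30)], aq, ProbeDesignParams()) == []

    def test_raising_similarity_never_adds_candidates(self, query_set):
        cons = column_conservation(query_set)
        lax = ProbeDesignParams(min_column_similarity=0.90)
        strict = ProbeDesignParams(min_column_similarity=0.98)
        n_lax = len(extract_candidates(find_conserved_blocks(cons, lax), query_set, lax))
        n_strict = len(
            extract_candidates(find_conserved_blocks(cons, strict), query_set, strict)
        )
        assert n_strict <= n_lax


class TestRefineCandidates:
    def _query(self, seed=1, ncol=300):
        rng = np.random.default_rng(seed)
        row = "".join(rng.choice(list("ACGT"), size=ncol))
        aq = _aqs([row, row], orf_ranges={"ORF1": (0, 150), "ORF2": (150, ncol)})
        return aq, row

    def test_cross_orf_candidate_removed(self):
        rng = np.random.default_rng(2)
        shared = "".join(rng.choice(list("ACGT"), size=50))
        filler = "".join(rng.choice(list("ACGT"), size=50))
        row = shared + filler + shared + filler  # ORF1 50-mer recurs in ORF2
        aq = _aqs([row, row], orf_ranges={"ORF1": (0, 100), "ORF2": (100, 200)})
        cands = [Candidate(shared, "ORF1", 0)]
        with pytest.raises(ValueError, match="no probes survive"):
            refine_candidates(cands, aq, {"d": "T" * 100})

    def test_minimal_decoy_hit_count_wins(self):
        aq, row = self._query()
        c1 = Candidate(row[10:60], "ORF1", 10)
        c2 = Candidate(row[160:210], "ORF2", 160)
        sep = "G" * 10
        decoy = {"d": sep.join([c1.sequence] * 3 + [c2.sequence] * 7)}
        result = refine_candidates([c1, c2], aq, decoy)
        assert [p.sequence for p in result.probes] == [c1.sequence]

    def test_overlapping_candidates_keep_leftmost(self):
        aq, row = self._query()
        c1 = Candidate(row[10:60], "ORF1", 10)
        c2 = Candidate(row[40:90], "ORF1", 40)  # overlaps c1 by 20 columns
        result = refine_candidates([c1, c2], aq, {"d": "T" * 100})
        assert [p.sequence for p in result.probes] == [c1.sequence]

    def test_step2_minimality_invariant(self, query_set, decoy):
        from l1pattern.probe_design import _count_exact_hits

        cons = column_conservation(query_set)
        params = ProbeDesignParams()
        cands = extract_candidates(find_conserved_blocks(cons, params), query_set, params)
        kept = refine_candidates(cands, query_set, decoy)
        decoy_seqs = list(decoy.values())
        kept_hits = {_count_exact_hits(p.sequence, decoy_seqs) for p in kept.probes}
        all_hits = [_count_exact_hits(c.sequence, decoy_seqs) for c in cands]
        assert kept_hits == {min(all_hits)}


class TestComputeLayout:
    def test_two_member_gap_average(self):
        rng = np.random.default_rng(3)
        p1 = "".join(rng.choice(list("ACGT"), size=50))
        p2 = "".join(rng.choice(list("ACGT"), size=50))
        mk = lambda gap: p1 + "".join(rng.choice(list("ACGT"), size=gap - 50)) + p2
        r1, r2 = mk(500), mk(520)
        r1 += "T" * (len(r2) - len(r1))
        aq = _aqs([r1, r2], orf_ranges={"ORF1": (0, len(r2))})
        provisional = ProbeSet(
            [Probe("a", p1, "ORF1", 0, 0), Probe("b", p2, "ORF1", 500, 0)], [500], 10
        )
        final = compute_layout(provisional, aq)
        assert final.adjacent_distances == [510]
        assert final.probes[0].avg_offset_element == 0

    def test_probeset_ordering_invariant_after_design(self, probeset):
        offsets = [p.avg_offset_element for p in probeset.probes]
        assert offsets == sorted(offsets)
        assert all(b > a for a, b in zip(offsets, offsets[1:]))
        assert len(probeset.adjacent_distances) == len(probeset) - 1
        assert all(d > 0 for d in probeset.adjacent_distances)

    def test_recovers_planted_block_layout(self, model, probeset):
        """Average probe gaps must match the generator's block spacing to
        within a couple of bases (members carry small deletions)."""
        starts = [a for _, (a, b) in model.conserved_blocks]
        planted_gaps = [b - a for a, b in zip(starts, starts[1:])]
        assert len(probeset) == len(starts)
        for got, want in zip(probeset.adjacent_distances, planted_gaps):
            assert abs(got - want) <= 2

    def test_expected_probe_counts_per_region(self, probeset):
        regions = [p.region for p in probeset.probes]
        assert regions.count("ORF1") == 5
        assert regions.count("ORF2") == 11


class TestProbeSetIO:
    def test_round_trip(self, probeset, tmp_path):
        fa, meta = tmp_path / "p.fa", tmp_path / "p.tsv"
        probeset.write(fa, meta)
        back = ProbeSet.read(fa, meta)
        assert back.probes == probeset.probes
        assert back.adjacent_distances == probeset.adjacent_distances
        assert back.avg_tail_length == probeset.avg_tail_length

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ProbeSet(
                [Probe("a", "ACGT", "ORF1", 10, 0), Probe("b", "ACGT", "ORF1", 5, 0)],
                [5],
                0,
            )
        with pytest.raises(ValueError, match="non-ACGT"):
            ProbeSet([Probe("a", "ACNT", "ORF1", 0, 0)], [], 0)
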