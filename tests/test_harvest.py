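"""Domain harvesting: PSSM construction, iterative search, completeness
rule, pseudodimer splitting, aCD detection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import get3atlas as g
from get3atlas.harvest import (_AA_INDEX, DomainHit, align_to_match_columns,
                               find_domains)
from get3atlas.records import AMINO_ACIDS


def random_seed_alignment(rng, rows=5, width=30):
    aa = list(AMINO_ACIDS)
    return g.AlignmentBlock([
        (f"r{i}", "".join(rng.choice(aa, size=width))) for i in range(rows)])


class TestBuildProfile:
    def test_consensus_outscores_junk(self):
        seed = g.AlignmentBlock([("a", "ACDE"), ("b", "ACDE")])
        prof = g.build_profile(seed)
        assert prof.score_sequence("ACDE") > prof.score_sequence("WWWW")

    def test_large_pseudocount_flattens_scores(self):
        seed = g.AlignmentBlock([("a", "ACDE"), ("b", "ACDE")])
        prof = g.build_profile(seed, pseudocount=1e9)
        assert np.allclose(prof.match_scores[:, :20], 0.0, atol=1e-6)

    def test_matches_per_column_tally(self, rng):
        """Log-odds recomputed column by column from raw counts."""
        seed = random_seed_alignment(rng)
        prof = g.build_profile(seed, pseudocount=1.3)
        counts_total = np.zeros(20)
        for _, row in seed.rows:
            for c in row:
                counts_total[_AA_INDEX[c]] += 1
        bg = (counts_total + 1.0) / (counts_total.sum() + 20.0)
        for col in range(seed.width):
            obs = np.zeros(20)
            for _, row in seed.rows:
                obs[_AA_INDEX[row[col]]] += 1
            n = obs.sum()
            expect = np.log2((obs + 1.3 * bg) / ((n + 1.3) * bg))
            assert np.allclose(prof.match_scores[col, :20], expect, atol=1e-9)

    def test_gappy_columns_excluded(self):
        seed = g.AlignmentBlock([("a", "A-CDE"), ("b", "A-CDE"),
                                 ("c", "AWCDE"), ("d", "A-CDE")])
        prof = g.build_profile(seed)
        assert prof.width == 4           # column 2 is 75% gaps

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2 rows"):
            g.build_profile(g.AlignmentBlock([("a", "ACDE")]))


def _embed(rng, domain, flank):
    aa = list(AMINO_ACIDS)
    pre = "".join(rng.choice(aa, size=flank))
    post = "".join(rng.choice(aa, size=flank))
    return pre + domain + post


class TestIterativeSearch:
    def test_seed_member_recovered_with_tight_interval(self, rng):
        seed = random_seed_alignment(rng, rows=4, width=60)
        prof = g.build_profile(seed)
        domain = seed.rows[0][1]
        db = [g.SequenceRecord("q", _embed(rng, domain, 25))]
        hits = g.iterative_search(prof, db, iterations=1, score_threshold=20)
        assert hits and hits[0].parent_id == "q"
        assert abs(hits[0].start - 26) <= 2 and abs(hits[0].end - 85) <= 2
        assert abs(hits[0].q_start - 1) <= 2 and abs(hits[0].q_end - 60) <= 2

    def test_shuffled_sequences_score_below_calibrated_threshold(self, rng):
        seed = random_seed_alignment(rng, rows=4, width=60)
        prof = g.build_profile(seed)
        member = g.SequenceRecord("m", seed.rows[0][1])
        thr = g.calibrate_score_threshold(prof, [member], n_shuffles=200, seed=5)
        shuffled = []
        for i in range(30):
            resid = np.array(list(member.residues))
            rng.shuffle(resid)
            shuffled.append(g.SequenceRecord(f"s{i}", "".join(resid)))
        hits = g.iterative_search(prof, shuffled, iterations=1,
                                  score_threshold=thr)
        assert hits == []
        # while the true member scores far above it
        assert prof.score_sequence(member.residues) > thr

    def test_single_iteration_equals_plain_search(self, rng):
        seed = random_seed_alignment(rng, rows=4, width=40)
        prof = g.build_profile(seed)
        db = [g.SequenceRecord(f"q{i}", _embed(rng, seed.rows[i % 4][1], 10))
              for i in range(6)]
        one = g.iterative_search(prof, db, iterations=1, score_threshold=15)
        plain = sorted((h for s in db for h in find_domains(prof, s, 15)),
                       key=lambda h: -h.score)
        assert [(h.parent_id, h.start, h.end, h.score) for h in one] == \
               [(h.parent_id, h.start, h.end, h.score) for h in plain]

    def test_empty_database_empty_result(self, rng):
        prof = g.build_profile(random_seed_alignment(rng))
        assert g.iterative_search(prof, [], score_threshold=10) == []

    def test_hit_set_nested_in_threshold(self, rng):
        seed = random_seed_alignment(rng, rows=4, width=50)
        prof = g.build_profile(seed)
        db = [g.SequenceRecord(f"q{i}", _embed(rng, seed.rows[i % 4][1], 15))
              for i in range(8)]
        lo = {(h.parent_id, h.start) for h in
              g.iterative_search(prof, db, iterations=1, score_threshold=10)}
        hi = {(h.parent_id, h.start) for h in
              g.iterative_search(prof, db, iterations=1, score_threshold=40)}
        assert hi <= lo


class TestCompleteness:
    def test_90_percent_boundary(self):
        keep = DomainHit("p", 1, 297, 1, 297, 50.0)
        drop = DomainHit("p", 1, 296, 1, 296, 50.0)
        out = g.completeness_filter([keep, drop], best_query_length=330)
        assert out == [keep]          # 297/330 = 0.900 kept, 296/330 removed

    def test_fraction_zero_keeps_all(self):
        hits = [DomainHit("p", 5, 10, 2, 7, 1.0)]
        assert g.completeness_filter(hits, 330, fraction=0.0) == hits

    @given(st.lists(st.tuples(st.integers(1, 200), st.integers(1, 200)),
                    max_size=20),
           st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_fraction(self, spans, f1, f2):
        hits = [DomainHit("p", 1, 1, min(a, b), max(a, b), 1.0)
                for a, b in spans]
        lo, hi = sorted([f1, f2])
        kept_hi = g.completeness_filter(hits, 200, fraction=hi)
        kept_lo = g.completeness_filter(hits, 200, fraction=lo)
        assert set(map(id, kept_hi)) <= set(map(id, kept_lo))


class TestPseudodimerSplit:
    def test_forced_midpoint(self):
        p = g.SequenceRecord("p", "A" * 800)
        n, c = g.split_pseudodimer(p, (10, 380), (420, 790))
        assert n.interval == (1, 400) and c.interval == (401, 800)
        assert n.partner_id == "p_C" and c.partner_id == "p_N"
        assert n.provenance == "pseudodimer_N" and c.provenance == "pseudodimer_C"

    def test_adjacent_boundary(self):
        p = g.SequenceRecord("p", "W" * 700)
        n, c = g.split_pseudodimer(p, (1, 350), (351, 700))
        assert n.interval == (1, 350) and c.interval == (351, 700)

    def test_overlap_rejected(self):
        p = g.SequenceRecord("p", "W" * 100)
        with pytest.raises(ValueError):
            g.split_pseudodimer(p, (1, 60), (50, 100))

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_halves_tile_parent(self, data):
        L = data.draw(st.integers(10, 500))
        e1 = data.draw(st.integers(2, L - 3))
        s2 = data.draw(st.integers(e1 + 1, L - 1))
        residues = "".join(data.draw(st.sampled_from(AMINO_ACIDS))
                           for _ in range(7)) * (L // 7 + 1)
        p = g.SequenceRecord("p", residues[:L])
        n, c = g.split_pseudodimer(p, (1, e1), (s2, L))
        assert n.residues + c.residues == p.residues
        assert n.interval[1] + 1 == c.interval[0]

    def test_multidomain_recursive_split_tiles(self):
        p = g.SequenceRecord("p", "ACDEFGHIKL" * 30)
        recs = g.split_multidomain(p, [(10, 80), (110, 180), (220, 290)])
        assert "".join(r.residues for r in recs) == p.residues
        assert [r.interval[0] for r in recs] == [1, 96, 201]


class TestAcdDetection:
    def test_verbatim_consensus_detected_and_shuffle_rejected(self, rng):
        seed = random_seed_alignment(rng, rows=3, width=50)
        prof = g.build_profile(seed)
        member = g.SequenceRecord("m", _embed(rng, seed.rows[0][1], 30))
        thr = g.calibrate_score_threshold(prof, [member], n_shuffles=200, seed=9)
        flag, interval = g.detect_acd(member, prof, thr)
        assert flag and interval is not None
        resid = np.array(list(member.residues))
        rng.shuffle(resid)
        flag2, _ = g.detect_acd(g.SequenceRecord("s", "".join(resid)), prof, thr)
        assert not flag2

    def test_empty_sequence_impossible(self):
        with pytest.raises(ValueError):
            g.SequenceRecord("x", "")


class TestAlignToMatchColumns:
    def test_member_realigned_exactly(self, rng):
        seed = random_seed_alignment(rng, rows=4, width=45)
        prof = g.build_profile(seed)
        row = seed.rows[2][1]
        assert align_to_match_columns(prof, row) == row
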