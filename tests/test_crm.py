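"""CRM clustering, fusion/extension and summaries."""

import itertools

import numpy as np
import pytest

from crmscan.conservation import ConservedHit
from crmscan.crm import (CRM, call_crms, calibrate_score_threshold,
                         fuse_and_extend, read_crms_json, score_window,
                         summarize, write_crms_json)
from crmscan.scan import BindingSiteHit


def chit(start, score, matrix="M1", seq="chr1", width=8):
    h = BindingSiteHit(matrix, seq, start, start + width, "+", score / 2)
    return ConservedHit(h, (), float(score), None)


def brute_force_crms(hits, window_bp, k, min_hits, threshold):
    """Independent oracle: enumerate every anchored window, then greedy."""
    per_seq = {}
    for h in sorted(hits, key=lambda h: (h.seq_id, h.start)):
        per_seq.setdefault(h.seq_id, []).append(h)
    candidates = []
    for seq_id, seq_hits in per_seq.items():
        for i in range(len(seq_hits)):
            window = [h for h in seq_hits[i:]
                      if h.start < seq_hits[i].start + window_bp]
            if len(window) < min_hits:
                continue
            by_matrix = {}
            for h in window:
                by_matrix.setdefault(h.matrix_id, []).append(h)
            if len(by_matrix) == 1:
                chosen = sorted(window,
                                key=lambda h: (-h.combined_score, h.start))[:k]
            else:
                best = [sorted(g, key=lambda h: (-h.combined_score, h.start))[0]
                        for g in by_matrix.values()]
                chosen = sorted(best,
                                key=lambda h: (-h.combined_score, h.start))[:k]
            score = sum(h.combined_score for h in chosen)
            if score >= threshold:
                candidates.append((score, seq_id,
                                   min(h.start for h in chosen),
                                   max(h.end for h in chosen)))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    picked = []
    for score, seq_id, start, end in candidates:
        if all(not (s == seq_id and start < e and b < end)
               for _, s, b, e in picked):
            picked.append((score, seq_id, start, end))
    return sorted(picked, key=lambda c: (c[1], c[2]))


class TestCallCrms:
    def test_homotypic_cluster_sums_top_hits(self):
        hits = [chit(0, 4), chit(50, 4), chit(100, 4)]
        crms = call_crms(hits, score_threshold=10)
        assert len(crms) == 1
        assert crms[0].score == pytest.approx(12.0)
        assert crms[0].tag_matrices == ("M1",)
        assert crms[0].start == 0 and crms[0].end == 108

    def test_oligotypic_takes_best_hit_per_matrix(self):
        hits = [chit(0, 4, "M1"), chit(20, 6, "M1"), chit(40, 5, "M2"),
                chit(60, 2, "M2")]
        crms = call_crms(hits, min_hits=3, score_threshold=10)
        assert len(crms) == 1
        assert crms[0].score == pytest.approx(11.0)  # 6 (M1) + 5 (M2)
        assert set(crms[0].tag_matrices) == {"M1", "M2"}
        # trimmed span 20..48 holds the two contributing hits only
        assert (crms[0].start, crms[0].end) == (20, 48)
        assert crms[0].n_sites == 2

    def test_top_k_distinct_matrices_limit(self):
        hits = [chit(i * 30, 10 - i, f"M{i}") for i in range(7)]
        crms = call_crms(hits, k=5, min_hits=3, score_threshold=1)
        assert len(crms[0].tag_matrices) == 5
        assert crms[0].score == pytest.approx(10 + 9 + 8 + 7 + 6)

    def test_distant_clusters_are_never_merged(self):
        cluster = [chit(0, 20), chit(30, 20), chit(60, 20)]
        far = [chit(5000 + s.start, s.combined_score) for s in cluster]
        far = [chit(5000, 20), chit(5030, 20), chit(5060, 20)]
        crms = call_crms(cluster + far, window_bp=1000, score_threshold=10)
        assert len(crms) == 2

    def test_min_hits_filters_sparse_windows(self):
        assert call_crms([chit(0, 50), chit(10, 50)], min_hits=3) == []
        assert call_crms([]) == []

    def test_score_rederives_from_stored_hits(self, fixture_conserved):
        for c in call_crms(fixture_conserved):
            assert c.score == pytest.approx(
                sum(h.combined_score for h in c.hits))
            assert c.start == min(h.start for h in c.hits)
            assert c.end == max(h.end for h in c.hits)
            assert set(c.tag_matrices) == {h.matrix_id for h in c.hits}
            assert len(c.tag_matrices) <= 5

    def test_output_non_overlapping_per_sequence(self, fixture_conserved):
        crms = call_crms(fixture_conserved)
        for a, b in itertools.combinations(crms, 2):
            if a.seq_id == b.seq_id:
                assert a.end <= b.start or b.end <= a.start

    def test_raising_threshold_never_increases_count(self, fixture_conserved):
        counts = [len(call_crms(fixture_conserved, score_threshold=t))
                  for t in (20, 45, 80, 120, 200)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        hits = []
        for _ in range(int(rng.integers(5, 25))):
            hits.append(chit(int(rng.integers(0, 3000)),
                             float(rng.uniform(1, 10)),
                             matrix=f"M{rng.integers(1, 4)}",
                             seq=f"chr{rng.integers(1, 3)}"))
        params = dict(window_bp=400, k=3, min_hits=2, score_threshold=8.0)
        got = [(c.score, c.seq_id, c.start, c.end)
               for c in call_crms(hits, **params)]
        expected = brute_force_crms(hits, 400, 3, 2, 8.0)
        assert [(s, a, b) for _, s, a, b in got] == \
               [(s, a, b) for _, s, a, b in expected]
        assert np.allclose([g[0] for g in got], [e[0] for e in expected])


class TestFuseAndExtend:
    LENGTHS = {"chr1": 10_000}

    def crm(self, start, end, cid="C1", seq="chr1"):
        return CRM(cid, seq, start, end, 50.0, ("M1",), (), 3)

    def test_close_crms_fuse_and_gain_flanks(self):
        regions = fuse_and_extend([self.crm(1000, 1200, "C1"),
                                   self.crm(1300, 1500, "C2")], self.LENGTHS)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (800, 1700)
        assert r.source_crms == ("C1", "C2")

    def test_left_clip_at_sequence_start(self):
        r = fuse_and_extend([self.crm(50, 250)], self.LENGTHS)[0]
        assert (r.start, r.end) == (0, 450)

    def test_right_clip_at_sequence_end(self):
        r = fuse_and_extend([self.crm(9900, 9950)], self.LENGTHS)[0]
        assert (r.start, r.end) == (9700, 10_000)

    def test_distant_crms_stay_separate(self):
        regions = fuse_and_extend([self.crm(1000, 1200, "C1"),
                                   self.crm(3000, 3200, "C2")], self.LENGTHS)
        assert [(r.start, r.end) for r in regions] == [(800, 1400),
                                                       (2800, 3400)]

    def test_every_region_contains_its_sources(self, fixture_crms, bundle):
        regions = fuse_and_extend(fixture_crms, bundle.seq_lengths)
        by_id = {c.crm_id: c for c in fixture_crms}
        for r in regions:
            for cid in r.source_crms:
                c = by_id[cid]
                assert r.start <= c.start and c.end <= r.end


class TestSummaries:
    def test_known_lengths(self):
        crms = [CRM(f"C{i}", "chr1", 0, n, 1.0, ("M1",), (), 5)
                for i, n in enumerate((100, 136, 500))]
        s = summarize(crms)
        assert s["mean_length"] == pytest.approx(245.333, abs=1e-3)
        assert s["median_length"] == 136
        assert s["mean_sites"] == 5

    def test_single_crm(self):
        s = summarize([CRM("C1", "chr1", 10, 110, 1.0, ("M1",), (), 2)])
        assert s["mean_length"] == s["median_length"] == 100

    def test_empty_list(self):
        s = summarize([])
        assert s == {"count": 0, "mean_length": None, "median_length": None,
                     "mean_sites": None}

    def test_fixture_summary_tracks_planted_ground_truth(self, fixture_crms,
                                                         bundle):
        s = summarize(fixture_crms)
        planted_lengths = [p.end - p.start for p in bundle.planted]
        # trimmed calls can only shrink relative to the planted spans
        assert s["count"] >= len(bundle.planted)
        assert s["mean_length"] <= np.mean(planted_lengths) * 1.5


class TestJsonRoundtrip:
    def test_crms_survive_json(self, tmp_path, fixture_crms):
        path = tmp_path / "crms.json"
        write_crms_json(fixture_crms, path)
        back = read_crms_json(path)
        for a, b in zip(back, fixture_crms):
            assert (a.crm_id, a.seq_id, a.start, a.end, a.tag_matrices,
                    a.n_sites) == (b.crm_id, b.seq_id, b.start, b.end,
                                   b.tag_matrices, b.n_sites)
            assert a.score == pytest.approx(b.score)
            assert a.score == pytest.approx(
                sum(h.combined_score for h in a.hits))


def test_calibrated_threshold_separates_clusters_from_shuffle(rng):
    # 60 strong hits clustered in 6 tight groups on a 100 kb sequence
    hits = []
    for g in range(6):
        base = 5000 + g * 15_000
        hits.extend(chit(base + j * 40, 25) for j in range(10))
    threshold = calibrate_score_threshold(hits, {"chr1": 100_000}, rng,
                                          n_shuffles=10)
    crms = call_crms(hits, score_threshold=threshold)
    assert threshold > 0
    # every call lies inside a planted cluster (a 10-hit homotypic cluster
    # may legitimately split into two top-5 calls), and every cluster is hit
    clusters = [(5000 + g * 15_000, 5000 + g * 15_000 + 9 * 40 + 8)
                for g in range(6)]
    for c in crms:
        assert any(c.start >= a and c.end <= b for a, b in clusters)
    for a, b in clusters:
        assert any(c.start >= a and c.end <= b for c in crms)
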