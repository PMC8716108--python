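import pytest

from termtte.formats_io import (
    EndCoverageTrack,
    FormatError,
    TranscriptionUnitAnnotation,
)
from termtte.tts_caller import (
    TTSCandidate,
    assign_primary,
    call_tts_ncrna,
    find_candidates,
    replicate_consensus,
    search_window,
    utr3_length,
)


def brute_force_candidates(track, window, strand, ratio_min=1.1, diff_min=5):
    """Independent oracle: literal evaluation of 'ratio > 1.1 AND diff > 5'
    at every window position."""
    lo, hi = window
    hits = []
    for p in range(lo, hi + 1):
        nxt = p + 1 if strand == "+" else p - 1
        m1, p1 = track[p], track[nxt]
        if m1 <= 0:
            continue
        ratio_pass = (m1 / p1 > ratio_min) if p1 > 0 else True
        if ratio_pass and (m1 - p1) > diff_min:
            hits.append(p)
    return hits


def make_track(counts, replicate=1, strand="+", condition="WT"):
    return EndCoverageTrack(condition, replicate, strand,
                            {p: float(v) for p, v in counts.items()}, "c")


class TestSearchWindow:
    def _tu(self, strand, stop3, span=(1, 1000)):
        lo = min(span[0], stop3)
        hi = max(span[1], stop3)
        return TranscriptionUnitAnnotation("t", "c", strand, lo, hi, stop3)

    def test_plus_strand_rule(self):
        assert search_window(self._tu("+", 1000), 5000) == (1001, 1200)

    def test_minus_strand_mirror(self):
        assert search_window(self._tu("-", 1000), 5000) == (800, 999)

    def test_clipped_at_genome_end(self):
        assert search_window(self._tu("+", 4950), 5000) == (4951, 5000)

    def test_entirely_outside_genome_is_error(self):
        with pytest.raises(FormatError):
            search_window(self._tu("+", 5000, span=(1, 5000)), 5000)


class TestFilters:
    def test_direct_filter_evaluation(self):
        # -1 = 20, +1 = 10: ratio 2.0 > 1.1 and diff 10 > 5 -> pass
        track = make_track({30: 20, 31: 10})
        assert [c.pos for c in find_candidates(track, (25, 30), "+")] == [30]

    def test_small_difference_fails(self):
        track = make_track({30: 7, 31: 6})
        assert find_candidates(track, (25, 30), "+") == []

    def test_zero_downstream_passes_ratio(self):
        track = make_track({30: 6})
        assert [c.pos for c in find_candidates(track, (25, 35), "+")] == [30]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_on_50nt_toy(self, strand):
        # hand-built 50-nt track exercising every filter edge:
        # big drops, sub-threshold ratios, sub-threshold diffs, zeros
        counts = {1: 100, 2: 100, 3: 40, 4: 40, 5: 36, 10: 6, 11: 0,
                  20: 50, 21: 46, 30: 12, 31: 6, 40: 7, 41: 1, 45: 5}
        track = make_track(counts, strand=strand)
        window = (1, 50)
        got = [c.pos for c in find_candidates(track, window, strand)]
        assert got == brute_force_candidates(track, window, strand)
        assert got  # the toy track does contain passing sites


class TestConsensus:
    def _cand(self, pos, rep, m1=50.0, p1=5.0):
        return TTSCandidate("t", "c", "+", pos, {rep: m1}, {rep: p1},
                            {rep: True})

    def test_intersection_kept(self):
        r1 = [self._cand(10, 1), self._cand(20, 1)]
        r2 = [self._cand(10, 2)]
        cons = replicate_consensus([r1, r2])
        assert [c.pos for c in cons] == [10]
        assert set(cons[0].reads_m1) == {1, 2}

    def test_single_replicate_site_dropped(self):
        cons = replicate_consensus([[self._cand(10, 1)], []])
        assert cons == []

    def test_idempotent_on_identical_replicates(self):
        r1 = [self._cand(10, 1), self._cand(20, 1)]
        r2 = [self._cand(10, 2), self._cand(20, 2)]
        assert [c.pos for c in replicate_consensus([r1, r2])] == [10, 20]

    def test_invariant_under_replicate_relabeling(self):
        r1 = [self._cand(10, 1, m1=60), self._cand(25, 1, m1=30)]
        r2 = [self._cand(10, 2, m1=40), self._cand(25, 2, m1=35)]
        a = replicate_consensus([r1, r2])
        b = replicate_consensus([r2, r1])
        assert [(c.pos, c.reads_m1) for c in a] == \
               [(c.pos, c.reads_m1) for c in b]


class TestAssignPrimary:
    TU = TranscriptionUnitAnnotation("t", "c", "+", 1, 100, 100)

    def _cand(self, pos, m1):
        return TTSCandidate("t", "c", "+", pos,
                            {1: m1, 2: m1}, {1: 1.0, 2: 1.0},
                            {1: True, 2: True})

    def _tracks(self):
        return {"WT": [make_track({}, 1), make_track({}, 2)]}

    def test_argmax_of_minus1_reads(self):
        sites = [self._cand(110, 50), self._cand(130, 120),
                 self._cand(150, 30)]
        recs = assign_primary(self.TU, sites, self._tracks())
        assert [r.pos for r in recs if r.is_primary] == [130]
        assert sum(r.is_primary for r in recs) == 1

    def test_tie_breaks_toward_stop_codon(self):
        # exhaustive over the two orders of a 2-site tie
        for sites in ([self._cand(110, 60), self._cand(140, 60)],
                      [self._cand(140, 60), self._cand(110, 60)]):
            recs = assign_primary(self.TU, sites, self._tracks())
            assert [r.pos for r in recs if r.is_primary] == [110]

    def test_single_site_is_primary(self):
        recs = assign_primary(self.TU, [self._cand(120, 20)], self._tracks())
        assert recs[0].is_primary

    def test_primary_minus1_mean_dominates_secondaries(self):
        sites = [self._cand(p, m) for p, m in [(105, 10), (120, 90),
                                               (160, 40)]]
        recs = assign_primary(self.TU, sites, self._tracks())
        prim = next(r for r in recs if r.is_primary)
        prim_m1 = sum(prim.reads_m1.values()) / len(prim.reads_m1)
        for r in recs:
            if not r.is_primary:
                assert sum(r.reads_m1.values()) / len(r.reads_m1) <= prim_m1


class TestUtr3Length:
    @pytest.mark.parametrize("strand,stop3,tts,expect", [
        ("+", 100, 101, 1),
        ("+", 100, 150, 50),
        ("-", 100, 50, 50),   # mirror of the +-strand case about stop3
        ("-", 100, 99, 1),
    ])
    def test_distance(self, strand, stop3, tts, expect):
        assert utr3_length(stop3, tts, strand) == expect

    def test_upstream_tts_is_error(self):
        with pytest.raises(ValueError):
            utr3_length(100, 90, "+")


class TestNcrnaMode:
    def _tu(self):
        return TranscriptionUnitAnnotation("nc1", "c", "+", 10, 25, None,
                                           biotype="ncRNA")

    def _tracks(self):
        t1 = make_track({30: 60, 31: 2}, 1)
        t2 = make_track({30: 55, 31: 3}, 2)
        return [t1, t2]

    def test_same_filters_as_coding_path(self):
        recs = call_tts_ncrna([self._tu()], {"nc1": (26, 45)},
                              self._tracks(), {"WT": self._tracks()})
        assert [r.pos for r in recs] == [30]
        assert recs[0].is_primary

    def test_missing_window_is_error(self):
        with pytest.raises(KeyError, match="nc1"):
            call_tts_ncrna([self._tu()], {}, self._tracks(),
                           {"WT": self._tracks()})

    def test_zero_length_window_yields_nothing(self):
        recs = call_tts_ncrna([self._tu()], {"nc1": (30, 29)},
                              self._tracks(), {"WT": self._tracks()})
        assert recs == []
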