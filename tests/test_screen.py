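"""Enhancer screen: peak intersection rules, summit windows, conservation."""

import numpy as np
import pandas as pd
import pytest

import fourcat as fc
from fourcat.screen import (
    SignalTrack,
    annotate_conservation,
    candidates_to_frame,
    max_signal_window,
    merge_windows,
    region_width,
    screen,
)

import _oracles

BED = ["chrom", "start", "end", "name"]


def _bed(rows):
    return pd.DataFrame(rows, columns=BED[: len(rows[0])] if rows else BED[:3])


def _signal(runs):
    return pd.DataFrame(runs, columns=["chrom", "start", "end", "value"])


def _random_track(rng, region_end=6_000):
    edges = np.sort(rng.choice(np.arange(0, region_end, 50), size=rng.integers(2, 12), replace=False))
    runs = []
    for s, e in zip(edges[:-1], edges[1:]):
        if rng.random() < 0.7:
            runs.append(("chr1", int(s), int(e), float(rng.integers(0, 20))))
    if not runs:
        runs = [("chr1", 0, region_end, 1.0)]
    return runs


class TestMaxSignalWindow:
    def test_uniform_signal_leftmost_tiebreak(self):
        sig = SignalTrack(_signal([("chr1", 0, 3_000, 2.0)]))
        s, e, v, zero = max_signal_window(sig, "chr1", 0, 3_000)
        assert (s, e) == (0, 1_000)
        assert v == pytest.approx(2_000.0)
        assert not zero

    def test_region_shorter_than_cap(self):
        sig = SignalTrack(_signal([("chr1", 0, 3_000, 1.0)]))
        s, e, _, _ = max_signal_window(sig, "chr1", 600, 1_200)
        assert (s, e) == (600, 1_200)

    def test_zero_signal_flagged(self):
        sig = SignalTrack(_signal([("chr1", 10_000, 11_000, 5.0)]))
        s, e, v, zero = max_signal_window(sig, "chr1", 0, 2_500)
        assert (s, e) == (0, 1_000) and v == 0.0 and zero

    def test_empty_region_rejected(self):
        sig = SignalTrack(_signal([("chr1", 0, 100, 1.0)]))
        with pytest.raises(ValueError):
            max_signal_window(sig, "chr1", 500, 500)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        runs = _random_track(rng)
        start = int(rng.integers(0, 2_000))
        end = start + int(rng.integers(1_200, 4_000))
        cap = int(rng.choice([500, 1_000, 1_500]))
        got = max_signal_window(SignalTrack(_signal(runs)), "chr1", start, end, cap)
        want = _oracles.max_window_scan([r[1:] for r in runs], start, end, cap)
        if want[2] <= 0:  # zero-signal convention: leftmost window, flagged
            assert got[3] and got[0] == start
        else:
            assert (got[0], got[1]) == (want[0], want[1])
            assert got[2] == pytest.approx(want[2])


SIG = _signal(
    [("chr1", 0, 10_200, 1.0), ("chr1", 10_200, 10_400, 50.0),
     ("chr1", 10_400, 100_000, 1.0)]
)


class TestScreenRules:
    INTER = _bed([("chr1", 10_000, 12_000), ("chr1", 20_000, 22_000),
                  ("chr1", 30_000, 32_000), ("chr2", 10_000, 12_000)])
    K27 = _bed([("chr1", 10_500, 11_000, "k1"), ("chr1", 30_100, 30_300, "k2")])
    ATAC = _bed([("chr1", 10_200, 10_800, "a1"), ("chr1", 20_100, 20_300, "a2"),
                 ("chr1", 30_400, 30_600, "a3")])
    PROM = _bed([("chr1", 31_900, 33_000, "p1")])

    def _run(self, **kw):
        args = dict(
            interactions=self.INTER, h3k27ac=self.K27, atac=self.ATAC,
            promoters=self.PROM, atac_signal=SIG, viewpoint_chrom="chr1",
        )
        args.update(kw)
        return screen(**args)

    def test_rules_applied_in_order(self):
        cands = self._run()
        # 20k window: ATAC only -> dropped; 30k: both marks but promoter -> dropped;
        # chr2: interchromosomal -> dropped; 10k survives
        assert len(cands) == 1
        c = cands[0]
        assert c.source_region == (10_000, 12_000)
        # max ATAC signal sits on the 50x run at 10,200-10,400
        assert c.start <= 10_200 and c.end >= 10_400
        assert c.h3k27ac_ids and c.atac_ids

    def test_empty_interactions_empty_output(self):
        assert self._run(interactions=_bed([])) == []

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError, match="atac_signal"):
            self._run(atac_signal=None)

    def test_adding_h3k27ac_never_removes_candidates(self):
        base = {c.source_region for c in self._run()}
        more = pd.concat(
            [self.K27, _bed([("chr1", 20_100, 20_200, "k3")])], ignore_index=True
        )
        grown = {c.source_region for c in self._run(h3k27ac=more)}
        assert base <= grown

    def test_adding_promoters_never_adds_candidates(self):
        base = {c.source_region for c in self._run()}
        more = pd.concat(
            [self.PROM, _bed([("chr1", 10_000, 10_100, "p2")])], ignore_index=True
        )
        shrunk = {c.source_region for c in self._run(promoters=more)}
        assert shrunk <= base

    def test_adjacent_windows_merge_into_one_region(self):
        inter = _bed([("chr1", 10_000, 12_000), ("chr1", 12_000, 14_000)])
        k27 = _bed([("chr1", 10_500, 13_500, "k")])
        atac = _bed([("chr1", 10_500, 13_500, "a")])
        cands = screen(inter, k27, atac, _bed([("chr1", 90_000, 91_000, "p")]),
                       SIG, "chr1")
        assert len(cands) == 1
        assert cands[0].source_region == (10_000, 14_000)

    def test_merge_windows_helper(self):
        assert merge_windows([(0, 2), (2, 4), (8, 10)]) == [(0, 4), (8, 10)]


class TestSimulatedScreen:
    def test_planted_enhancers_become_candidates(self, default_run):
        """Each condition-active planted summit yields a candidate within 500 bp."""
        for cond in ("quad", "sol"):
            cands = default_run.candidates[cond]
            active = [
                e for e in default_run.sim_config.planted if e.effect(cond) > 1
            ]
            for enh in active:
                assert any(
                    c.start - 500 <= enh.summit < c.end + 500 for c in cands
                ), f"{cond}: no candidate near summit {enh.summit}"

    def test_candidate_invariants(self, default_run):
        proms = default_run.tracks["promoters"]
        for cands in default_run.candidates.values():
            for c in cands:
                assert c.width <= 1_000
                assert c.source_region[0] <= c.start and c.end <= c.source_region[1]
                overlap = proms[
                    (proms["chrom"] == c.chrom)
                    & (proms["start"] < c.end)
                    & (proms["end"] > c.start)
                ]
                assert overlap.empty, "candidate overlaps a promoter"


class TestConservation:
    def _cands(self, spans):
        return [
            fc.CandidateEnhancer("chr1", s, e, (s, e), 1.0) for s, e in spans
        ]

    def test_fraction(self):
        cands = self._cands([(0, 500), (1_000, 1_500), (3_000, 3_400)])
        conserved = _bed([("chr1", 100, 200), ("chr1", 3_100, 3_200)])
        out, frac = annotate_conservation(cands, conserved)
        assert [c.conserved for c in out] == [True, False, True]
        assert frac == pytest.approx(2 / 3)

    def test_empty_conserved_set(self):
        out, frac = annotate_conservation(self._cands([(0, 500)]), _bed([]))
        assert frac == 0.0 and out[0].conserved is False

    def test_abutting_element_not_conserved(self):
        out, frac = annotate_conservation(
            self._cands([(0, 500)]), _bed([("chr1", 500, 600)])
        )
        assert out[0].conserved is False


class TestRegionWidth:
    def test_printed_span(self):
        width, kb = region_width("chr11:67,104,519–67,142,456")
        assert width == 37_937
        assert kb == 38

    def test_hyphen_and_plain_digits(self):
        assert region_width("chr1:0-1,000") == (1_000, 1)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            region_width("chr1:5-5")
        with pytest.raises(ValueError):
            region_width("chr1:100-50")

    def test_unparseable(self):
        with pytest.raises(ValueError):
            region_width("not a span")


def test_candidates_frame_columns(default_run):
    df = candidates_to_frame(default_run.candidates["quad"])
    assert list(df.columns)[:4] == ["chrom", "start", "end", "name"]
    assert (df["end"] - df["start"] <= 1_000).all()
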