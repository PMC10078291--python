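import numpy as np
import pandas as pd
import pytest

from kineticnet import accessibility as acc
from kineticnet.io import Gene, SignalTrack
from kineticnet.proseq import (call_divergent_peaks, composite_profile,
                               differential_transcription, expression_matrix,
                               pause_metrics)
from kineticnet.simulate import make_tracks, simulate_proseq


def _track_plus(chrom="c", peak_at=1032, peak_val=10.0, body=(1300, 6000, 0.5)):
    t = SignalTrack()
    t.add(chrom, peak_at, peak_at + 1, peak_val, "+")
    t.add(chrom, *body[:2], body[2], "+")
    return t


class TestPauseMetrics:
    def test_summit_and_region_from_unique_maximum(self):
        gene = Gene("c", 1000, 9000, "g", "+")
        track = _track_plus(peak_at=1032)  # max at TSS+32
        m = pause_metrics(gene, track)
        assert m.summit == 1032
        assert (m.pause_start, m.pause_end) == (1007, 1057)

    def test_pause_index_arithmetic(self):
        # pause sum 100 over 50 bp vs body sum 500 over 5000 bp -> PI = 20
        gene = Gene("c", 1000, 1281 + 5000, "g", "+")
        track = SignalTrack()
        track.add("c", 1007, 1031, 2.0, "+")
        track.add("c", 1031, 1032, 4.0, "+")  # unique max -> summit 1031
        track.add("c", 1032, 1056, 2.0, "+")  # pause sum = 48 + 4 + 48 = 100
        track.add("c", 1281, 1281 + 5000, 0.1, "+")  # body sum 500 over 5000
        m = pause_metrics(gene, track)
        assert m.summit == 1031
        assert m.pause_density == pytest.approx(2.0)
        assert m.body_density == pytest.approx(0.1)
        assert m.pause_index == pytest.approx(20.0)

    def test_minus_strand_gene_mirrors_plus(self):
        plus_gene = Gene("c", 1000, 9000, "gp", "+")
        plus_track = _track_plus()
        mp = pause_metrics(plus_gene, plus_track)
        # mirror everything around position 5000
        minus_gene = Gene("c", 10000 - 9000, 10000 - 1000, "gm", "-")
        minus_track = SignalTrack()
        minus_track.add("c", 10000 - 1033, 10000 - 1032, 10.0, "-")
        minus_track.add("c", 10000 - 6000, 10000 - 1300, 0.5, "-")
        mm = pause_metrics(minus_gene, minus_track)
        assert mm.summit == 10000 - 1 - 1032
        assert mm.pause_index == pytest.approx(mp.pause_index)

    def test_zero_signal_flags_gene(self):
        gene = Gene("c", 1000, 9000, "g", "+")
        m = pause_metrics(gene, SignalTrack())
        assert not m.ok and m.summit is None

    def test_tie_broken_toward_tss(self):
        gene = Gene("c", 1000, 9000, "g", "+")
        track = SignalTrack()
        track.add("c", 1030, 1031, 7.0, "+")
        track.add("c", 1060, 1061, 7.0, "+")
        track.add("c", 1300, 6000, 0.1, "+")
        assert pause_metrics(gene, track).summit == 1030

    def test_short_gene_rejected(self):
        gene = Gene("c", 1000, 1900, "g", "+")
        with pytest.raises(ValueError):
            pause_metrics(gene, _track_plus())


class TestComposite:
    def test_single_anchor_equals_its_window(self):
        track = _track_plus()
        prof = composite_profile([("c", 1032, "+")], track, half_window=100)
        assert prof.loc[prof["offset"] == 0, "sense"].iloc[0] == 10.0
        assert prof.loc[prof["offset"] == 50, "sense"].iloc[0] == 0.0

    def test_all_zero_signal_gives_zero_composite(self):
        prof = composite_profile([("c", 500, "+"), ("c", 900, "-")],
                                 SignalTrack(), half_window=50)
        assert (prof["sense"] == 0).all() and (prof["antisense"] == 0).all()

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError):
            composite_profile([], SignalTrack())

    def test_minus_anchor_mirrors_offsets(self):
        track = SignalTrack()
        track.add("c", 1100, 1101, 5.0, "-")  # 100 bp downstream of a '-' anchor
        prof = composite_profile([("c", 1200, "-")], track, half_window=150)
        assert prof.loc[prof["offset"] == 100, "sense"].iloc[0] == 5.0

    def test_removing_promoter_anchors_collapses_divergent_peaks(self, small_truth):
        """Composites over promoter-proximal SP motifs show the divergent
        two-peak structure; excluding promoters collapses it."""
        track = make_tracks(small_truth, 0)
        hits = small_truth.hits
        sp = hits[hits["family"] == "SP"]
        peaks = {p.name: p for p in small_truth.peaks}
        promoter, distal = [], []
        tss_by_chrom = [(g.chrom, g.tss, g.strand) for g in small_truth.genes]
        for row in sp.itertuples():
            pk = peaks[row.peak]
            pos = pk.start + row.offset + 4
            near = [s for c, t, s in tss_by_chrom
                    if c == pk.chrom and abs(pos - t) <= 400]
            (promoter if near else distal).append((pk.chrom, pos, near[0] if near else "+"))
        assert len(promoter) >= 5
        prof_all = composite_profile(promoter + distal, track, half_window=300)
        prof_distal = composite_profile(distal, track, half_window=300) if distal \
            else prof_all.assign(antisense=0.0)
        assert prof_all["antisense"].max() > 2 * max(
            prof_distal["antisense"].max(), 1e-9)


class TestDifferentialTranscription:
    def test_zero_count_genes_excluded_not_called(self, rng):
        design = acc.make_design([0, 20], 3)
        counts = pd.DataFrame(rng.poisson(100, size=(30, 6)),
                              columns=design.index, dtype=float)
        counts.iloc[0] = 0.0
        calls = differential_transcription(counts, design, 0, 20)
        assert counts.index[0] not in set(calls["feature"])
        assert set(calls["gene_class"]) <= {"activated", "repressed", "unchanged"}

    def test_planted_activation_called_up(self, rng):
        design = acc.make_design([0, 20], 3)
        ok = 0
        for _ in range(30):
            base = np.full(100, 800.0)
            a = rng.poisson(base, size=(3, 100)).T
            b = rng.poisson(base, size=(3, 100)).T
            b[:5] = rng.poisson(base[:5] * 2, size=(3, 5)).T
            counts = pd.DataFrame(np.hstack([a, b]), columns=design.index)
            calls = differential_transcription(counts, design, 0, 20)
            ok += (calls.iloc[:5]["gene_class"] == "activated").all()
        assert ok / 30 >= 0.95


class TestExpressionAndDivergence:
    def test_expression_floor_quantile(self):
        density = pd.DataFrame({0: [0.0, 1.0, 2.0, 3.0, 4.0]},
                               index=list("abcde"))
        ex = expression_matrix(density, floor_quantile=0.25)
        # floor = 25th pct of nonzero {1,2,3,4} = 1.75
        assert ex[0].tolist() == [False, False, True, True, True]

    def test_divergent_caller_pairs_opposing_peaks(self):
        track = SignalTrack()
        track.add("c", 500, 501, 5.0, "-")
        track.add("c", 640, 641, 6.0, "+")  # 140 bp downstream of the minus peak
        track.add("c", 5000, 5001, 6.0, "+")  # no upstream minus partner
        calls = call_divergent_peaks(track, "c", 0, 6000, threshold=1.0)
        assert len(calls) == 1
        assert calls[0][2] == 500 and calls[0][3] == 640


class TestPauseIndexOnTruth:
    def test_pause_release_increase_lowers_median_pi(self, small_truth,
                                                     small_config):
        """Genes with planted f_rel > 1 between 0 and 20 min show a drop in
        median pause index between those time points."""
        pause, body = simulate_proseq(small_truth, small_config)
        design = small_config.design
        gr_targets = [g for g, r in small_truth.gene_roles.items()
                      if r == "target:GR"]
        def median_pi(t):
            cols = design.index[design["time"] == t]
            p = pause.loc[gr_targets, cols].mean(axis=1) / 50.0
            L = pd.Series({g: small_truth.gene_base_params[g].L
                           for g in gr_targets})
            b = body.loc[gr_targets, cols].mean(axis=1) / L
            return float((p / b).median())
        assert median_pi(20) < median_pi(0)

    def test_track_pi_matches_compartment_prediction(self, small_truth):
        track = make_tracks(small_truth, 0)
        g = small_truth.genes[0]
        m = pause_metrics(g, track)
        P = small_truth.pause_occupancy.at[g.name, 0]
        b = small_truth.body_density.at[g.name, 0]
        assert m.ok
        assert m.pause_index == pytest.approx((P / 50.0) / b, rel=0.05)
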