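import numpy as np
import pandas as pd
import pytest

from kineticnet.cdf import FactorConstraint
from kineticnet.io import Gene, Peak, PeakSet
from kineticnet.network import (CisEdge, Network, NetworkRules, TransEdge,
                                annotate_attenuation, downstream_reach,
                                infer_cis_edges, infer_trans_edges,
                                subnetwork_stats)

from _oracles import oracle_cis_edges, oracle_trans_edges
from _instances import random_rule_instance as _random_instance

TIMES = (0, 20, 40, 60, 120, 180, 240)
CALL_COLS = ["feature", "time_a", "time_b", "mean_a", "mean_b", "log2fc",
             "pvalue", "qvalue", "direction"]


def _calls(rows):
    """rows: (feature, ta, tb, direction) for significant calls only."""
    full = []
    feats = sorted({r[0] for r in rows})
    sig = {(r[0], r[1], r[2]): r[3] for r in rows}
    for f in feats:
        for i, a in enumerate(TIMES):
            for b in TIMES[i + 1:]:
                d = sig.get((f, a, b), "none")
                full.append((f, a, b, 1, 1, 0.0, 0.5, 0.5, d))
    return pd.DataFrame(full, columns=CALL_COLS)


def _hits(pairs):
    return pd.DataFrame([(p, f, 0, "+", 8.0, 0.9, 1e-5) for p, f in pairs],
                        columns=["peak", "family", "offset", "strand", "score",
                                 "score_fraction", "pvalue"])


def _expressed(genes, value=True):
    return pd.DataFrame(value, index=list(genes), columns=list(TIMES))


class TestTransRules:
    FUNC = {"GR": "opener", "SP": "opener", "TWIST": "closer", "AP1": "opener"}
    FAMG = {"GR": "Nr3c1", "SP": "Sp1", "TWIST": "Twist2", "AP1": "Fosl1"}

    def test_gr_cocktail_binding_edge(self):
        atac = _calls([("re1", 0, 20, "up")])
        gene_calls = _calls([])
        edges = infer_trans_edges(atac, _hits([("re1", "GR")]), self.FUNC,
                                  self.FAMG, gene_calls,
                                  _expressed(self.FAMG.values()))
        assert [e.key for e in edges] == [("GR", "re1", 0, 20, "binding")]

    def test_gr_binding_restricted_to_first_40_minutes(self):
        atac = _calls([("re1", 0, 60, "up")])
        edges = infer_trans_edges(atac, _hits([("re1", "GR")]), self.FUNC,
                                  self.FAMG, _calls([]),
                                  _expressed(self.FAMG.values()))
        assert edges == []

    def test_sp_late_decrease_is_dissociation(self):
        atac = _calls([("re1", 60, 120, "down")])
        gene_calls = _calls([("Sp1", 40, 60, "down")])
        edges = infer_trans_edges(atac, _hits([("re1", "SP")]), self.FUNC,
                                  self.FAMG, gene_calls,
                                  _expressed(self.FAMG.values()))
        assert [e.key for e in edges] == [("SP", "re1", 60, 120, "dissociation")]

    def test_sp_has_no_edges_before_40_minutes(self):
        atac = _calls([("re1", 20, 40, "down")])
        gene_calls = _calls([("Sp1", 0, 20, "down")])
        edges = infer_trans_edges(atac, _hits([("re1", "SP")]), self.FUNC,
                                  self.FAMG, gene_calls,
                                  _expressed(self.FAMG.values()))
        assert edges == []

    def test_twist_needs_prior_gene_activation(self):
        # RE rises 0-20 while the family gene is not yet activated: no edge
        atac = _calls([("re1", 0, 20, "down"), ("re2", 20, 40, "down")])
        gene_calls = _calls([("Twist2", 0, 20, "up")])
        edges = infer_trans_edges(atac, _hits([("re1", "TWIST"),
                                               ("re2", "TWIST")]),
                                  self.FUNC, self.FAMG, gene_calls,
                                  _expressed(self.FAMG.values()))
        assert [e.key for e in edges] == [("TWIST", "re2", 20, 40, "binding")]

    def test_gr_dissociation_needs_prior_binding_at_same_re(self):
        atac = _calls([("re1", 0, 20, "up"), ("re1", 20, 60, "down"),
                       ("re2", 20, 60, "down")])
        edges = infer_trans_edges(atac, _hits([("re1", "GR"), ("re2", "GR")]),
                                  self.FUNC, self.FAMG, _calls([]),
                                  _expressed(self.FAMG.values()))
        keys = {e.key for e in edges}
        assert ("GR", "re1", 20, 60, "dissociation") in keys
        assert not any(k[1] == "re2" and k[4] == "dissociation" for k in keys)

    def test_unexpressed_family_gets_no_edges(self):
        atac = _calls([("re1", 0, 20, "up")])
        edges = infer_trans_edges(atac, _hits([("re1", "GR")]), self.FUNC,
                                  self.FAMG, _calls([]),
                                  _expressed(self.FAMG.values(), False))
        assert edges == []

    def test_unassigned_function_skipped_with_warning(self):
        atac = _calls([("re1", 0, 20, "up")])
        with pytest.warns(UserWarning, match="no assigned function"):
            edges = infer_trans_edges(atac, _hits([("re1", "NRF")]),
                                      {"NRF": "unassigned"}, {}, _calls([]),
                                      _expressed([]))
        assert edges == []


class TestCisRules:
    def _setup(self, re_pos=3000, gene_start=6000, max_d=10_000):
        peaks = PeakSet([Peak("c", re_pos, re_pos + 400, "re1")])
        genes = [Gene("c", gene_start, gene_start + 8000, "g1", "+")]
        trans = [TransEdge("GR", "re1", 0, 20, "binding")]
        gene_calls = _calls([("g1", 0, 20, "up")])
        constraints = {"GR": FactorConstraint("GR", [(0, 20)], max_d)}
        return peaks, genes, trans, gene_calls, constraints

    def test_activation_edge_within_distance(self):
        peaks, genes, trans, calls, cons = self._setup()
        edges = infer_cis_edges(trans, peaks, genes, calls,
                                {"GR": "opener"}, cons)
        assert len(edges) == 1
        e = edges[0]
        assert (e.re_id, e.gene, e.sign) == ("re1", "g1", "activation")
        assert e.families == frozenset({"GR"})

    def test_gene_beyond_10kb_gap_excluded(self):
        peaks, genes, trans, calls, cons = self._setup(re_pos=3000,
                                                       gene_start=14_000)
        # gap = 14000 - 3400 = 10600 > 10 kb
        assert infer_cis_edges(trans, peaks, genes, calls,
                               {"GR": "opener"}, cons) == []

    def test_factor_distance_cap_tighter_than_10kb(self):
        # summit at 3200, TSS at 6000: 2800 > a 2000-bp factor cap
        peaks, genes, trans, calls, cons = self._setup(max_d=2000)
        assert infer_cis_edges(trans, peaks, genes, calls,
                               {"GR": "opener"}, cons) == []

    def test_non_overlapping_intervals_excluded(self):
        peaks, genes, trans, calls, cons = self._setup()
        late = _calls([("g1", 60, 120, "up")])
        assert infer_cis_edges(trans, peaks, genes, late,
                               {"GR": "opener"}, cons) == []

    def test_factor_without_constraint_draws_no_edges(self):
        peaks, genes, trans, calls, _ = self._setup()
        cons = {"GR": FactorConstraint("GR", [], None)}
        assert infer_cis_edges(trans, peaks, genes, calls,
                               {"GR": "opener"}, cons) == []

    def test_strict_interval_equality_switch(self):
        peaks, genes, trans, calls, cons = self._setup()
        rules = NetworkRules(strict_interval_equality=True)
        calls2 = _calls([("g1", 0, 40, "up")])  # overlaps but not equal
        assert infer_cis_edges(trans, peaks, genes, calls2,
                               {"GR": "opener"}, cons, rules) == []
        assert len(infer_cis_edges(trans, peaks, genes, calls,
                                   {"GR": "opener"}, cons, rules)) == 1


class TestAttenuation:
    def test_reversed_gene_marks_cis_edge_attenuated(self):
        cis = [CisEdge("re1", "g1", 0, 20, frozenset({"GR"}), "activation"),
               CisEdge("re1", "g2", 0, 20, frozenset({"GR"}), "activation")]
        gene_calls = _calls([("g1", 0, 20, "up"), ("g1", 60, 240, "down"),
                             ("g2", 0, 20, "up")])
        _, out = annotate_attenuation([], cis, _calls([]), gene_calls,
                                      {"GR": "opener"})
        assert out[0].attenuated is True  # activated then repressed
        assert out[1].attenuated is False  # sustained activation

    def test_re_reversal_marks_trans_edge_attenuated(self):
        trans = [TransEdge("GR", "re1", 0, 20, "binding")]
        atac = _calls([("re1", 0, 20, "up"), ("re1", 40, 120, "down")])
        out, _ = annotate_attenuation(trans, [], atac, _calls([]),
                                      {"GR": "opener"})
        assert out[0].attenuated is True

    def test_planted_attenuation_fraction_recovered(self, default_truth):
        early = [g for g, r in default_truth.gene_roles.items()
                 if r in ("target:AP1", "target:CEBP", "target:SHARED")]
        by_gene = {}
        for e in default_truth.network.cis_edges:
            if e.gene in early and e.sign == "activation":
                by_gene.setdefault(e.gene, []).append(e.attenuated)
        frac = np.mean([any(flags) for flags in by_gene.values()])
        planted = np.mean([g in default_truth.attenuated_genes for g in early])
        assert planted == pytest.approx(0.6, abs=0.06)
        assert frac == pytest.approx(planted, abs=0.05)


class TestSubnetworksAndReach:
    def _toy(self):
        peaks = PeakSet([Peak("c", i * 1000, i * 1000 + 400, f"re{i}")
                         for i in range(3)])
        genes = [Gene("c", 20_000 * (i + 1), 20_000 * (i + 1) + 8000,
                      f"g{i}", "+") for i in range(2)]
        trans = [TransEdge("AP1", "re0", 0, 20, "binding"),
                 TransEdge("AP1", "re1", 0, 20, "binding"),
                 TransEdge("GR", "re1", 0, 20, "binding"),
                 TransEdge("GR", "re2", 0, 20, "binding")]
        cis = [CisEdge("re0", "g0", 0, 20, frozenset({"AP1"}), "activation"),
               CisEdge("re1", "g1", 0, 20, frozenset({"AP1", "GR"}),
                       "activation")]
        return Network(peaks, genes, trans, cis,
                       {"AP1": "opener", "GR": "opener"},
                       {"AP1": "g0", "GR": "gX"})

    def test_solely_vs_combinatorial_genes(self):
        stats = subnetwork_stats(self._toy(), "AP1",
                                 activator_families=["AP1", "GR"])
        assert stats["solely_regulated_genes"] == {"g0"}
        assert stats["combinatorial_genes"] == {"g1"}
        assert stats["bound_res_without_targets"] == set()
        gr = subnetwork_stats(self._toy(), "GR",
                              activator_families=["AP1", "GR"])
        assert gr["bound_res_without_targets"] == {"re2"}

    def test_re_combination_classes_enumeration(self):
        stats = subnetwork_stats(self._toy(), "AP1",
                                 activator_families=["AP1", "GR"])
        assert stats["re_combination_classes"] == {
            frozenset({"AP1"}): 1, frozenset({"AP1", "GR"}): 1,
            frozenset({"GR"}): 1}
        four = subnetwork_stats(self._toy(), "AP1",
                                activator_families=list("ABCD"))
        assert four["n_possible_re_classes"] == 15

    def test_counts_match_brute_force_on_random_toy_networks(self, rng):
        fams = ["A", "B", "C"]
        for _ in range(50):
            n_re, n_g = 12, 8
            peaks = PeakSet([Peak("c", i * 1000, i * 1000 + 400, f"re{i}")
                             for i in range(n_re)])
            genes = [Gene("c", 100_000 + 20_000 * i, 108_000 + 20_000 * i,
                          f"g{i}", "+") for i in range(n_g)]
            trans, cis = [], []
            for i in range(n_re):
                for f in fams:
                    if rng.random() < 0.3:
                        trans.append(TransEdge(f, f"re{i}", 0, 20, "binding"))
            bound = {}
            for e in trans:
                bound.setdefault(e.re_id, set()).add(e.family)
            for re_id, fs in bound.items():
                if rng.random() < 0.6:
                    g = f"g{int(rng.integers(n_g))}"
                    cis.append(CisEdge(re_id, g, 0, 20, frozenset(fs),
                                       "activation"))
            net = Network(peaks, genes, trans, cis,
                          {f: "opener" for f in fams}, {})
            stats = subnetwork_stats(net, "A", activator_families=fams)
            # brute force from the raw edge lists
            gene_fams = {}
            for e in cis:
                gene_fams.setdefault(e.gene, set()).update(e.families)
            solely = {g for g, fs in gene_fams.items() if fs == {"A"}}
            combo = {g for g, fs in gene_fams.items()
                     if "A" in fs and len(fs) > 1}
            assert stats["solely_regulated_genes"] == solely
            assert stats["combinatorial_genes"] == combo
            classes = {}
            for fs in bound.values():
                classes[frozenset(fs)] = classes.get(frozenset(fs), 0) + 1
            assert stats["re_combination_classes"] == classes

    def test_two_hop_time_respecting_chain(self):
        peaks = PeakSet([Peak("c", 0, 400, "re0")])
        genes = [Gene("c", 20_000, 28_000, "tf", "+"),
                 Gene("c", 40_000, 48_000, "g1", "+")]
        trans = [TransEdge("F", "re0", 20, 40, "binding")]
        cis = [CisEdge("re0", "g1", 40, 60, frozenset({"F"}), "activation")]
        net = Network(peaks, genes, trans, cis, {"F": "opener"}, {"F": "tf"})
        r = downstream_reach(net, "tf")
        assert r["res"] == {"re0"} and r["genes"] == {"g1"}

    def test_edge_earlier_than_arrival_not_traversed(self):
        peaks = PeakSet([Peak("c", 0, 400, "re0")])
        genes = [Gene("c", 20_000, 28_000, "tf", "+"),
                 Gene("c", 40_000, 48_000, "g1", "+")]
        trans = [TransEdge("F", "re0", 40, 60, "binding")]
        cis = [CisEdge("re0", "g1", 0, 20, frozenset({"F"}), "activation")]
        net = Network(peaks, genes, trans, cis, {"F": "opener"}, {"F": "tf"})
        r = downstream_reach(net, "tf")
        assert r["res"] == {"re0"} and r["genes"] == set()


class TestOracleEquivalence:
    def test_rule_engine_matches_brute_force_on_random_instances(self, rng):
        """Spot-check equivalence (the 50-genome sweep runs in acceptance)."""
        for _ in range(5):
            self._check_one(rng)

    @staticmethod
    def _check_one(rng):
        (peaks, genes, functions, family_genes, atac_calls, gene_calls,
         hit_pairs, expressed, constraints, rules) = _random_instance(rng)
        hits = _hits(hit_pairs)
        trans = infer_trans_edges(atac_calls, hits, functions, family_genes,
                                  gene_calls, expressed, rules)
        cis = infer_cis_edges(trans, peaks, genes, gene_calls, functions,
                              constraints, rules)

        sig_atac = [(r.feature, int(r.time_a), int(r.time_b), r.direction)
                    for r in atac_calls.itertuples() if r.direction != "none"]
        sig_gene = [(r.feature, int(r.time_a), int(r.time_b), r.direction)
                    for r in gene_calls.itertuples() if r.direction != "none"]
        peak_families = {}
        for p, f in hit_pairs:
            peak_families.setdefault(p, set()).add(f)
        up_ends, down_ends = {}, {}
        for g, a, b, d in sig_gene:
            (up_ends if d == "up" else down_ends).setdefault(g, []).append(b)
        exp_map = {(g, t): bool(expressed.at[g, t])
                   for g in expressed.index for t in expressed.columns}
        oracle_t = oracle_trans_edges(
            sig_atac, peak_families, functions, family_genes, up_ends,
            down_ends, exp_map, set(rules.cocktail_families),
            rules.cocktail_end, rules.binding_end, rules.min_start)
        assert {e.key for e in trans} == oracle_t

        peak_coords = {p.name: (p.start, p.end) for p in peaks}
        summits = {p.name: p.summit for p in peaks}
        gene_coords = {g.name: (g.start, g.end) for g in genes}
        tss = {g.name: g.tss for g in genes}
        cons = {f: (set(c.comparisons), c.max_distance_bp)
                for f, c in constraints.items()}
        oracle_c = oracle_cis_edges(oracle_t, peak_coords, summits,
                                    gene_coords, tss, sig_gene, functions,
                                    cons)
        got = {(e.re_id, e.gene, e.t_a, e.t_b, e.sign, e.families)
               for e in cis}
        assert got == oracle_c


class TestValidator:
    def test_valid_network_passes(self, default_truth):
        report = default_truth.network.validate(default_truth.time_points)
        assert report["valid"], report["violations"][:5]

    def test_orphan_cis_edge_detected(self):
        peaks = PeakSet([Peak("c", 0, 400, "re0")])
        genes = [Gene("c", 2000, 10_000, "g1", "+")]
        net = Network(peaks, genes, [],
                      [CisEdge("re0", "g1", 0, 20, frozenset({"F"}),
                               "activation")],
                      {"F": "opener"}, {})
        report = net.validate(TIMES)
        assert not report["valid"]
        assert any("no overlapping trans edge" in v
                   for v in report["violations"])

    def test_offdesign_interval_detected(self):
        peaks = PeakSet([Peak("c", 0, 400, "re0")])
        net = Network(peaks, [], [TransEdge("F", "re0", 0, 33, "binding")],
                      [], {"F": "opener"}, {})
        assert not net.validate(TIMES)["valid"]
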