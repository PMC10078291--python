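"""Rule-based inference of the bipartite kinetic regulatory network.

Nodes are TF families (anchored at the gene encoding the family member where
known), regulatory elements (REs, accessibility peaks), and genes.  A
*trans-edge* (family -> RE) asserts an inferred change in factor occupancy:

1. the RE is an accessibility peak;
2. the family's binding motif is present in the RE;
3. accessibility changes significantly between two time points;
4. the direction of the change matches the family's molecular function
   (opener binding or closer dissociation opens; the converse closes);
5. the family's gene is expressed at the appropriate time point (later for
   binding, earlier for dissociation) and — for families not directly
   activated by the stimulus — significantly activated (binding) or
   repressed (dissociation) no later than the edge's start;
6. families activated directly by the adipogenic cocktail (AP-1, CEBP, GR by
   default) get early binding edges without a gene-activation requirement.

GR binding is restricted to the first 40 min; later significant decreases at
GR-bound REs become *dissociation* edges.  SP edges are restricted to >= 40
min.  A *cis-edge* (RE -> gene) requires the RE within 10 kb of the gene
body, covariation of accessibility and transcription over overlapping time
intervals with signs consistent with every contributing family, and the
factor-specific comparison set and maximal actionable distance from the CDF
analysis.  An edge is *attenuated* when its RE/gene later reverses
significantly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Gene, Peak, PeakSet

__all__ = [
    "NetworkRules",
    "TransEdge",
    "CisEdge",
    "Network",
    "expected_gene_direction",
    "expected_accessibility_direction",
    "infer_trans_edges",
    "infer_cis_edges",
    "annotate_attenuation",
    "build_network",
    "subnetwork_stats",
    "downstream_reach",
]


@dataclass(frozen=True)
class NetworkRules:
    """Thresholds and temporal windows for edge inference (all configurable)."""

    cocktail_families: frozenset = frozenset({"AP1", "CEBP", "GR"})
    # cocktail exemption: binding edges ending by this time need no gene activation
    cocktail_window_end: tuple = (("AP1", 20), ("CEBP", 20), ("GR", 40))
    # binding edges for these families must end by the given minute
    binding_window_end: tuple = (("GR", 40),)
    # no edges for these families before the given minute
    min_edge_start: tuple = (("SP", 40),)
    # curated direction-of-effect overrides (the SP family scores as a closer
    # from single-motif peaks but is a canonical activator losing occupancy)
    function_overrides: tuple = (("SP", "opener"),)
    max_cis_gap_bp: int = 10_000
    strict_interval_equality: bool = False
    expression_floor_quantile: float = 0.25

    def _map(self, name):
        return dict(getattr(self, name))

    @property
    def cocktail_end(self) -> dict:
        return self._map("cocktail_window_end")

    @property
    def binding_end(self) -> dict:
        return self._map("binding_window_end")

    @property
    def min_start(self) -> dict:
        return self._map("min_edge_start")

    @property
    def overrides(self) -> dict:
        return self._map("function_overrides")


@dataclass(frozen=True)
class TransEdge:
    family: str
    re_id: str
    t_a: int
    t_b: int
    attribute: str  # binding | dissociation
    attenuated: bool = False

    def __post_init__(self):
        if self.t_a >= self.t_b:
            raise ValueError("edge interval must have t_a < t_b")
        if self.attribute not in ("binding", "dissociation"):
            raise ValueError(f"bad attribute {self.attribute!r}")

    @property
    def key(self):
        return (self.family, self.re_id, self.t_a, self.t_b, self.attribute)


@dataclass(frozen=True)
class CisEdge:
    re_id: str
    gene: str
    t_a: int
    t_b: int
    families: frozenset
    sign: str  # activation | repression
    attenuated: bool = False

    def __post_init__(self):
        if self.t_a >= self.t_b:
            raise ValueError("edge interval must have t_a < t_b")
        if self.sign not in ("activation", "repression"):
            raise ValueError(f"bad sign {self.sign!r}")
        if not self.families:
            raise ValueError("cis-edge needs >=1 contributing family")

    @property
    def key(self):
        return (self.re_id, self.gene, self.t_a, self.t_b, self.sign)


def expected_gene_direction(function: str, attribute: str) -> str:
    """Transcriptional effect implied by a trans-edge: 'up' or 'down'."""
    if function == "opener":
        return "up" if attribute == "binding" else "down"
    if function == "closer":
        return "down" if attribute == "binding" else "up"
    raise ValueError(f"unassigned function {function!r}")


def expected_accessibility_direction(function: str, attribute: str) -> str:
    """Accessibility change implied by a trans-edge: 'up' or 'down'."""
    if function == "opener":
        return "up" if attribute == "binding" else "down"
    if function == "closer":
        return "down" if attribute == "binding" else "up"
    raise ValueError(f"unassigned function {function!r}")


def _resolve_functions(functions: dict, rules: NetworkRules) -> dict:
    out = dict(functions)
    out.update(rules.overrides)
    return out


def _change_end_times(gene_calls: pd.DataFrame, gene: str, direction: str) -> list[int]:
    sub = gene_calls[(gene_calls["feature"] == gene)
                     & (gene_calls["direction"] == direction)]
    return sorted(sub["time_b"].tolist())


def infer_trans_edges(atac_calls: pd.DataFrame, hits: pd.DataFrame,
                      functions: dict, family_genes: dict,
                      gene_calls: pd.DataFrame, expressed: pd.DataFrame,
                      rules: NetworkRules = NetworkRules()) -> list[TransEdge]:
    """Apply trans-edge rules (1)-(6); see the module docstring.

    ``expressed`` is a genes x time-points boolean frame (body density above
    the expression floor).  Families with an unassigned function are skipped
    with a warning.
    """
    functions = _resolve_functions(functions, rules)
    sig = atac_calls[atac_calls["direction"] != "none"]
    fams_by_peak = hits.groupby("peak")["family"].agg(set).to_dict()

    act_end: dict[str, list[int]] = {}
    rep_end: dict[str, list[int]] = {}
    for fam, g in family_genes.items():
        act_end[fam] = _change_end_times(gene_calls, g, "up")
        rep_end[fam] = _change_end_times(gene_calls, g, "down")

    def is_expressed(fam: str, t: int) -> bool:
        g = family_genes.get(fam)
        return g is not None and g in expressed.index and bool(expressed.at[g, t])

    warned: set[str] = set()
    binding: list[TransEdge] = []
    dissoc_candidates: list[tuple] = []
    for row in sig.itertuples():
        peak, t_a, t_b, direction = row.feature, int(row.time_a), int(row.time_b), row.direction
        for fam in sorted(fams_by_peak.get(peak, ())):
            func = functions.get(fam, "unassigned")
            if func == "unassigned":
                if fam not in warned:
                    warnings.warn(f"family {fam} has no assigned function; skipped")
                    warned.add(fam)
                continue
            attribute = ("binding"
                         if (direction == "up") == (func == "opener")
                         else "dissociation")
            if t_a < rules.min_start.get(fam, 0):
                continue
            if attribute == "binding":
                if t_b > rules.binding_end.get(fam, np.inf):
                    continue
                if not is_expressed(fam, t_b):
                    continue
                cocktail_ok = (fam in rules.cocktail_families
                               and t_b <= rules.cocktail_end.get(fam, 20))
                activated_ok = any(v <= t_a for v in act_end.get(fam, ()))
                if cocktail_ok or activated_ok:
                    binding.append(TransEdge(fam, peak, t_a, t_b, "binding"))
            else:
                dissoc_candidates.append((fam, peak, t_a, t_b))

    bind_end_by = {}
    for e in binding:
        bind_end_by.setdefault((e.family, e.re_id), []).append(e.t_b)
    dissociation = []
    for fam, peak, t_a, t_b in dissoc_candidates:
        if not is_expressed(fam, t_a):
            continue
        repressed_ok = any(v <= t_a for v in rep_end.get(fam, ()))
        prior_binding_ok = (fam in rules.cocktail_families and any(
            tb <= t_a for tb in bind_end_by.get((fam, peak), ())))
        if repressed_ok or prior_binding_ok:
            dissociation.append(TransEdge(fam, peak, t_a, t_b, "dissociation"))
    return sorted(binding + dissociation, key=lambda e: e.key)


def _summit_tss_distance(peak: Peak, gene: Gene) -> int:
    return abs(gene.tss - peak.summit)


def _body_gap(peak: Peak, gene: Gene) -> int:
    if peak.chrom != gene.chrom:
        return 10 ** 9
    if peak.end <= gene.start:
        return gene.start - peak.end
    if gene.end <= peak.start:
        return peak.start - gene.end
    return 0


def infer_cis_edges(trans_edges: list[TransEdge], peaks: PeakSet,
                    genes: list[Gene], gene_calls: pd.DataFrame,
                    functions: dict, constraints: dict,
                    rules: NetworkRules = NetworkRules()) -> list[CisEdge]:
    """Apply the cis-edge rule set; see the module docstring.

    ``constraints`` maps family -> :class:`FactorConstraint`; a family with
    no constraint (or no significant proximity signal) contributes to no
    cis-edges.
    """
    functions = _resolve_functions(functions, rules)
    te_by_re: dict[str, list[TransEdge]] = {}
    for te in trans_edges:
        te_by_re.setdefault(te.re_id, []).append(te)

    sig_by_gene = {
        g: sub for g, sub in
        gene_calls[gene_calls["direction"] != "none"].groupby("feature")
    }

    def constraint_ok(fam: str, gene: str, expected_dir: str) -> bool:
        c = constraints.get(fam)
        if c is None or c.max_distance_bp is None:
            return False
        sub = sig_by_gene.get(gene)
        if sub is None:
            return False
        comps = set(c.comparisons)
        match = sub[sub["direction"] == expected_dir]
        return any((int(r.time_a), int(r.time_b)) in comps for r in match.itertuples())

    edges: dict[tuple, set] = {}
    for re_id, te_list in te_by_re.items():
        peak = peaks[re_id]
        for gene in genes:
            if _body_gap(peak, gene) > rules.max_cis_gap_bp:
                continue
            sub = sig_by_gene.get(gene.name)
            if sub is None:
                continue
            for row in sub.itertuples():
                u, v, direction = int(row.time_a), int(row.time_b), row.direction
                fams = set()
                for te in te_list:
                    func = functions.get(te.family, "unassigned")
                    if func == "unassigned":
                        continue
                    if expected_gene_direction(func, te.attribute) != direction:
                        continue
                    if rules.strict_interval_equality:
                        if (te.t_a, te.t_b) != (u, v):
                            continue
                    elif not (te.t_a <= v and u <= te.t_b):
                        continue
                    c = constraints.get(te.family)
                    if c is None or c.max_distance_bp is None:
                        continue
                    if _summit_tss_distance(peak, gene) > c.max_distance_bp:
                        continue
                    if not constraint_ok(te.family, gene.name, direction):
                        continue
                    fams.add(te.family)
                if fams:
                    key = (re_id, gene.name, u, v,
                           "activation" if direction == "up" else "repression")
                    edges.setdefault(key, set()).update(fams)
    return sorted(
        (CisEdge(k[0], k[1], k[2], k[3], frozenset(f), k[4]) for k, f in edges.items()),
        key=lambda e: e.key)


def annotate_attenuation(trans_edges: list[TransEdge], cis_edges: list[CisEdge],
                         atac_calls: pd.DataFrame, gene_calls: pd.DataFrame,
                         functions: dict, rules: NetworkRules = NetworkRules(),
                         ) -> tuple[list[TransEdge], list[CisEdge]]:
    """Flag edges whose RE (trans) or gene (cis) later reverses significantly.

    A reversal is a significant change of opposite sign starting no earlier
    than the edge's end time.
    """
    functions = _resolve_functions(functions, rules)
    sig_atac = atac_calls[atac_calls["direction"] != "none"]
    sig_gene = gene_calls[gene_calls["direction"] != "none"]
    atac_by = {f: sub for f, sub in sig_atac.groupby("feature")}
    gene_by = {f: sub for f, sub in sig_gene.groupby("feature")}

    def has_reversal(sub, after: int, opposite: str) -> bool:
        if sub is None:
            return False
        hit = sub[(sub["direction"] == opposite) & (sub["time_a"] >= after)]
        return not hit.empty

    out_trans = []
    for e in trans_edges:
        acc_dir = expected_accessibility_direction(functions[e.family], e.attribute)
        opposite = "down" if acc_dir == "up" else "up"
        out_trans.append(replace(
            e, attenuated=has_reversal(atac_by.get(e.re_id), e.t_b, opposite)))
    out_cis = []
    for e in cis_edges:
        opposite = "down" if e.sign == "activation" else "up"
        out_cis.append(replace(
            e, attenuated=has_reversal(gene_by.get(e.gene), e.t_b, opposite)))
    return out_trans, out_cis


class Network:
    """The inferred bipartite directed graph plus its provenance tables."""

    def __init__(self, peaks: PeakSet, genes: list[Gene],
                 trans_edges: list[TransEdge], cis_edges: list[CisEdge],
                 functions: dict, family_genes: dict,
                 constraints: dict | None = None,
                 rules: NetworkRules = NetworkRules()):
        self.peaks = peaks
        self.genes = {g.name: g for g in genes}
        self.trans_edges = list(trans_edges)
        self.cis_edges = list(cis_edges)
        self.functions = dict(functions)
        self.family_genes = dict(family_genes)
        self.constraints = dict(constraints or {})
        self.rules = rules

    # -- export ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.trans_edges:
            rows.append((e.family, e.re_id, "trans", e.t_a, e.t_b, e.attribute,
                         e.attenuated, e.family))
        for e in self.cis_edges:
            rows.append((e.re_id, e.gene, "cis", e.t_a, e.t_b, e.sign,
                         e.attenuated, ",".join(sorted(e.families))))
        return pd.DataFrame(rows, columns=[
            "src", "dst", "edge_kind", "interval_start_min", "interval_end_min",
            "attribute", "attenuated", "families"])

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for fam in sorted({e.family for e in self.trans_edges}):
            g.add_node(f"family:{fam}", kind="family",
                       gene=self.family_genes.get(fam, ""))
        for e in self.trans_edges:
            g.add_node(f"re:{e.re_id}", kind="re")
            g.add_edge(f"family:{e.family}", f"re:{e.re_id}", edge_kind="trans",
                       t_a=e.t_a, t_b=e.t_b, attribute=e.attribute,
                       attenuated=e.attenuated)
        for e in self.cis_edges:
            g.add_node(f"re:{e.re_id}", kind="re")
            g.add_node(f"gene:{e.gene}", kind="gene")
            g.add_edge(f"re:{e.re_id}", f"gene:{e.gene}", edge_kind="cis",
                       t_a=e.t_a, t_b=e.t_b, attribute=e.sign,
                       attenuated=e.attenuated,
                       families=",".join(sorted(e.families)))
        return g

    # -- validation ------------------------------------------------------
    def validate(self, time_points=None) -> dict:
        """Check the structural invariants; returns {'valid', 'violations'}."""
        violations: list[str] = []
        functions = _resolve_functions(self.functions, self.rules)
        times = set(time_points) if time_points is not None else None

        te_by_re: dict[str, list[TransEdge]] = {}
        for e in self.trans_edges:
            te_by_re.setdefault(e.re_id, []).append(e)
            if times is not None and not {e.t_a, e.t_b} <= times:
                violations.append(f"trans edge {e.key}: interval off the design")
            if e.re_id not in self.peaks:
                violations.append(f"trans edge {e.key}: unknown RE")

        for e in self.cis_edges:
            if times is not None and not {e.t_a, e.t_b} <= times:
                violations.append(f"cis edge {e.key}: interval off the design")
            if e.re_id not in self.peaks or e.gene not in self.genes:
                violations.append(f"cis edge {e.key}: unknown node")
                continue
            peak, gene = self.peaks[e.re_id], self.genes[e.gene]
            if _body_gap(peak, gene) > self.rules.max_cis_gap_bp:
                violations.append(f"cis edge {e.key}: gene-body gap > "
                                  f"{self.rules.max_cis_gap_bp}")
            overlapping = [t for t in te_by_re.get(e.re_id, ())
                           if t.t_a <= e.t_b and e.t_a <= t.t_b]
            if not overlapping:
                violations.append(f"cis edge {e.key}: no overlapping trans edge")
            for fam in e.families:
                expected = expected_gene_direction(functions[fam], "binding")
                ok = any(
                    expected_gene_direction(functions[t.family], t.attribute)
                    == ("up" if e.sign == "activation" else "down")
                    for t in overlapping if t.family == fam)
                if not ok:
                    violations.append(
                        f"cis edge {e.key}: family {fam} sign-inconsistent")
                c = self.constraints.get(fam)
                if c is not None and c.max_distance_bp is not None:
                    if _summit_tss_distance(peak, gene) > c.max_distance_bp:
                        violations.append(
                            f"cis edge {e.key}: beyond {fam} actionable distance")
        return {"valid": not violations, "violations": violations,
                "n_trans": len(self.trans_edges), "n_cis": len(self.cis_edges)}


def build_network(peaks, genes, atac_calls, hits, functions, family_genes,
                  gene_calls, expressed, constraints,
                  rules: NetworkRules = NetworkRules()) -> Network:
    """Run trans- and cis-edge inference plus attenuation annotation."""
    trans = infer_trans_edges(atac_calls, hits, functions, family_genes,
                              gene_calls, expressed, rules)
    cis = infer_cis_edges(trans, peaks, genes, gene_calls, functions,
                          constraints, rules)
    trans, cis = annotate_attenuation(trans, cis, atac_calls, gene_calls,
                                      _resolve_functions(functions, rules), rules)
    return Network(peaks, genes, trans, cis, functions, family_genes,
                   constraints, rules)


def subnetwork_stats(network: Network, factor: str,
                     activator_families: list[str] | None = None) -> dict:
    """Counts for the factor-constrained subnetwork.

    Returns gene sets solely vs combinatorially regulated by ``factor``,
    factor-bound REs without downstream targets, and the counts of RE
    combination classes (nonempty subsets of activator families bound).
    """
    if activator_families is None:
        functions = _resolve_functions(network.functions, network.rules)
        activator_families = sorted(
            f for f, fn in functions.items() if fn == "opener")
    gene_fams: dict[str, set] = {}
    for e in network.cis_edges:
        gene_fams.setdefault(e.gene, set()).update(e.families)
    solely = {g for g, fams in gene_fams.items() if fams == {factor}}
    combinatorial = {g for g, fams in gene_fams.items()
                     if factor in fams and len(fams) > 1}

    res_bound = {e.re_id for e in network.trans_edges if e.family == factor}
    res_with_targets = {e.re_id for e in network.cis_edges}
    res_without_targets = res_bound - res_with_targets

    re_fams: dict[str, set] = {}
    for e in network.trans_edges:
        if e.family in activator_families:
            re_fams.setdefault(e.re_id, set()).add(e.family)
    classes: dict[frozenset, int] = {}
    for fams in re_fams.values():
        classes[frozenset(fams)] = classes.get(frozenset(fams), 0) + 1
    return {
        "factor": factor,
        "solely_regulated_genes": solely,
        "combinatorial_genes": combinatorial,
        "bound_res": res_bound,
        "bound_res_without_targets": res_without_targets,
        "re_combination_classes": classes,
        "n_possible_re_classes": 2 ** len(activator_families) - 1,
    }


def downstream_reach(network: Network, source_gene: str) -> dict:
    """REs and genes reachable from a gene node along time-respecting paths.

    An edge is admitted only when its interval starts no earlier than the
    start of the interval through which its source node was reached; the
    traversal keeps the minimal arrival start per node.
    """
    gene_of = network.family_genes
    fams_of_gene: dict[str, list[str]] = {}
    for fam, g in gene_of.items():
        fams_of_gene.setdefault(g, []).append(fam)
    te_by_fam: dict[str, list[TransEdge]] = {}
    for e in network.trans_edges:
        te_by_fam.setdefault(e.family, []).append(e)
    ce_by_re: dict[str, list[CisEdge]] = {}
    for e in network.cis_edges:
        ce_by_re.setdefault(e.re_id, []).append(e)

    arrival: dict[tuple, float] = {("gene", source_gene): -np.inf}
    work = [("gene", source_gene)]
    n_steps = 0
    limit = 10 * (len(network.trans_edges) + len(network.cis_edges) + 1) ** 2
    while work:
        n_steps += 1
        assert n_steps <= limit, "time-respecting traversal failed to terminate"
        kind, name = node = work.pop()
        t0 = arrival[node]
        if kind == "gene":
            for fam in fams_of_gene.get(name, ()):
                for e in te_by_fam.get(fam, ()):
                    if e.t_a >= t0:
                        nxt = ("re", e.re_id)
                        if arrival.get(nxt, np.inf) > e.t_a:
                            arrival[nxt] = e.t_a
                            work.append(nxt)
        else:
            for e in ce_by_re.get(name, ()):
                if e.t_a >= t0:
                    nxt = ("gene", e.gene)
                    if arrival.get(nxt, np.inf) > e.t_a:
                        arrival[nxt] = e.t_a
                        work.append(nxt)
    res = {n for k, n in arrival if k == "re"}
    genes = {n for k, n in arrival if k == "gene"} - {source_gene}
    return {"res": res, "genes": genes, "n_res": len(res), "n_genes": len(genes)}
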