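"""End-to-end orchestration: counts -> calls -> motifs -> CDF -> network.

The pipeline runs the stages in causal order (accessibility dynamics, motif
direction-of-effect, nascent-transcription calls, CDF distance constraints,
network construction, compartment fits, cooperation tables), writes every
intermediate to disk, and returns a JSON-serializable report.  Given a seed
the run is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accessibility as acc
from .cdf import derive_constraints, nearest_factor_distance
from .compartment import TwoCompartmentModel
from .cooperation import odds_ratio_ci, stratified_tables
from .io import write_genes, write_network, write_peaks
from .motifs import assign_direction, scan_peaks
from .network import (Network, NetworkRules, build_network, downstream_reach,
                      subnetwork_stats)
from .proseq import differential_transcription, expression_matrix
from .simulate import (SimConfig, TruthSet, simulate_atac, simulate_proseq,
                       simulate_truth)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_counts",
           "analyze_synthetic", "run_pipeline", "edge_sets", "precision_recall"]

log = logging.getLogger("kineticnet")


@dataclass
class PipelineConfig:
    """Configuration of a synthetic end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    rules: NetworkRules = field(default_factory=NetworkRules)
    out_dir: str | None = None
    noiseless: bool = False
    write_outputs: bool = True

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class AnalysisResult:
    """Everything the pipeline inferred from one count data set."""

    atac_calls: pd.DataFrame
    peak_classes: pd.Series
    hits: pd.DataFrame
    functions: dict
    gene_calls: pd.DataFrame
    expressed: pd.DataFrame
    constraints: dict
    network: Network
    body_norm: pd.DataFrame
    pause_norm: pd.DataFrame
    report: dict


def _pair_calls_transcription(body_counts, design, q):
    import itertools

    factors = acc.size_factors(body_counts, pseudocount=0.5)
    disp = acc.estimate_dispersions(body_counts, design, factors)
    times = sorted(design["time"].unique())
    frames = [differential_transcription(body_counts, design, a, b, q,
                                         factors=factors, dispersions=disp)
              for a, b in itertools.combinations(times, 2)]
    return pd.concat(frames, ignore_index=True), factors


def analyze_counts(peaks, genes, genome, atac_counts, pause_counts, body_counts,
                   design, seed: int, q_threshold: float = 0.05,
                   n_permutations: int = 300, motifs=None,
                   rules: NetworkRules = NetworkRules(),
                   gene_body_lengths: pd.Series | None = None,
                   family_genes: dict | None = None) -> AnalysisResult:
    """The full inference cascade on observed count matrices."""
    times = sorted(design["time"].unique())
    log.info("thresholds: q=%g permutations=%d seed=%d", q_threshold,
             n_permutations, seed)

    # 1. accessibility dynamics
    sf = acc.size_factors(atac_counts, pseudocount=0.5)
    atac_calls = acc.all_pairwise_calls(atac_counts, design, q_threshold, sf)
    peak_classes = acc.classify_all(atac_counts, design, atac_calls,
                                    q_threshold, sf)

    # 2. motif scan + direction of effect
    hits = scan_peaks(peaks, genome, motifs)
    functions, _isolated = assign_direction(hits, peak_classes.to_dict(), motifs)
    resolved = dict(functions)
    resolved.update(rules.overrides)

    # 3. nascent transcription
    gene_calls, body_sf = _pair_calls_transcription(body_counts, design,
                                                    q_threshold)
    body_norm = acc.normalized_counts(body_counts, body_sf)
    pause_norm = acc.normalized_counts(pause_counts, body_sf)
    if gene_body_lengths is None:
        gene_body_lengths = pd.Series(
            {g.name: float(len(g)) for g in genes})
    density = pd.DataFrame({
        t: body_norm[design.index[design["time"] == t]].mean(axis=1)
        / gene_body_lengths
        for t in times})
    expressed = expression_matrix(density, rules.expression_floor_quantile)

    # 4. CDF distance constraints
    constraints = derive_constraints(peaks, hits, atac_calls, gene_calls, genes,
                                     resolved, seed=seed,
                                     n_permutations=n_permutations)

    # 5. network
    if family_genes is None:
        family_genes = {f: f"{f}_gene" for f in resolved}
        family_genes = {f: g for f, g in family_genes.items()
                        if any(gene.name == g for gene in genes)}
    net = build_network(peaks, genes, atac_calls, hits, functions, family_genes,
                        gene_calls, expressed, constraints, rules)
    report = {"validator": net.validate(time_points=times),
              "n_trans_edges": len(net.trans_edges),
              "n_cis_edges": len(net.cis_edges),
              "functions": functions,
              "class_counts": peak_classes.value_counts().to_dict(),
              "constraints": {f: c.to_dict() for f, c in constraints.items()}}
    return AnalysisResult(atac_calls, peak_classes, hits, functions, gene_calls,
                          expressed, constraints, net, body_norm, pause_norm,
                          report)


def analyze_synthetic(config: SimConfig, noiseless: bool = False,
                      rules: NetworkRules = NetworkRules(),
                      truth: TruthSet | None = None
                      ) -> tuple[TruthSet, AnalysisResult]:
    """Simulate a time course and run the full inference on it."""
    if truth is None:
        truth = simulate_truth(config)
    atac = simulate_atac(truth, config, noiseless=noiseless)
    pause, body = simulate_proseq(truth, config, noiseless=noiseless)
    lengths = pd.Series({g.name: truth.gene_base_params[g.name].L
                         for g in truth.genes})
    result = analyze_counts(
        truth.peaks, truth.genes, truth.genome, atac, pause, body,
        config.design, seed=config.seed, q_threshold=config.q_threshold,
        n_permutations=config.n_permutations, motifs=truth.motifs, rules=rules,
        gene_body_lengths=lengths, family_genes=truth.family_genes)
    return truth, result


# ---------------------------------------------------------------------------
# evaluation against planted truth


def edge_sets(net: Network) -> set:
    """Hashable edge identity set (trans + cis) for precision/recall."""
    out = {("trans",) + e.key for e in net.trans_edges}
    out |= {("cis", e.re_id, e.gene, e.t_a, e.t_b, e.sign)
            for e in net.cis_edges}
    return out


def precision_recall(truth_net: Network, inferred_net: Network) -> dict:
    t, i = edge_sets(truth_net), edge_sets(inferred_net)
    tp = len(t & i)
    return {
        "precision": tp / len(i) if i else 1.0,
        "recall": tp / len(t) if t else 1.0,
        "n_truth": len(t),
        "n_inferred": len(i),
    }


# ---------------------------------------------------------------------------
# downstream summaries


def factor_fits(truth_or_result, result: AnalysisResult, design,
                factors=("GR", "SP")) -> dict:
    """Compartment-model fold-change fits on per-factor composite occupancy.

    For each factor the genes solely regulated by it are pooled; the mean
    normalized pause and body signal at the factor's first constrained
    comparison give the two occupancy snapshots.  The fitted fold changes
    are invariant to independent rescaling of the pause and body units
    (only the ratios P2/P1 and b2/b1 enter), so both snapshots are mapped
    to grid-friendly units (P1 = 5 polymerases, P1/b1 = 1250 bp) before
    fitting; the reported residency ratio is likewise scale-free.
    """
    out = {}
    times = sorted(design["time"].unique())
    for fam in factors:
        c = result.constraints.get(fam)
        if c is None or not c.comparisons:
            continue
        t1, t2 = c.comparisons[0]
        stats = subnetwork_stats(result.network, fam)
        gene_set = sorted(stats["solely_regulated_genes"])
        if len(gene_set) < 2:
            continue
        cols1 = design.index[design["time"] == t1]
        cols2 = design.index[design["time"] == t2]
        P1 = float(result.pause_norm.loc[gene_set, cols1].mean().mean())
        P2 = float(result.pause_norm.loc[gene_set, cols2].mean().mean())
        b1 = float(result.body_norm.loc[gene_set, cols1].mean().mean())
        b2 = float(result.body_norm.loc[gene_set, cols2].mean().mean())
        if min(P1, P2, b1, b2) <= 0:
            continue
        p_scale, b_scale = 5.0 / P1, (5.0 / 1250.0) / b1
        from .compartment import Occupancy

        try:
            fit = TwoCompartmentModel(
                Occupancy(P1 * p_scale, b1 * b_scale),
                Occupancy(P2 * p_scale, b2 * b_scale)).fit()
        except ValueError:
            continue
        out[fam] = {"comparison": [t1, t2], "n_genes": len(gene_set),
                    "f_init": fit.fold_changes.f_init,
                    "f_rel": fit.fold_changes.f_rel,
                    "residency_ratio": (fit.residency_after_s
                                        / fit.residency_before_s)}
    return out


def cooperation_summary(result: AnalysisResult, genes,
                        pairs=(("AP1", "GR", "up"), ("TWIST", "SP", "down")),
                        ) -> dict:
    """Stratified odds-ratio tables for factor pairs (Fig 6-style)."""
    out = {}
    hits, classes = result.hits, result.peak_classes
    dynamic_peaks = set(classes[classes != "nondynamic"].index)
    peak_by_name = {p.name: p for p in result.network.peaks}

    def proximal_genes(fam: str) -> set:
        c = result.constraints.get(fam)
        limit = c.max_distance_bp if (c and c.max_distance_bp) else None
        if limit is None:
            return set()
        fam_peaks = set(hits.loc[hits["family"] == fam, "peak"]) & dynamic_peaks
        by_chrom: dict[str, list[int]] = {}
        for p in fam_peaks:
            pk = peak_by_name[p]
            by_chrom.setdefault(pk.chrom, []).append(pk.summit)
        prox = set()
        for g in genes:
            summits = by_chrom.get(g.chrom)
            if summits and nearest_factor_distance([g.tss], summits)[0] <= limit:
                prox.add(g.name)
        return prox

    sig = result.gene_calls[result.gene_calls["direction"] != "none"]
    for fam_a, fam_b, direction in pairs:
        dynamic = set(sig.loc[sig["direction"] == direction, "feature"])
        tbl_absent, tbl_present = stratified_tables(
            [g.name for g in genes], dynamic, proximal_genes(fam_a),
            proximal_genes(fam_b))
        entry = {}
        for label, tbl in (("absent", tbl_absent), ("present", tbl_present)):
            if tbl.n == 0:
                entry[label] = {"table": [0, 0, 0, 0], "flag": "empty stratum"}
                continue
            ci = odds_ratio_ci(tbl)
            entry[label] = {"table": [tbl.a, tbl.b, tbl.c, tbl.d],
                            "odds_ratio": ci.odds_ratio,
                            "ci95": [ci.lower, ci.upper]}
        out[f"{fam_a}|{fam_b}"] = entry
    return out


def reach_ranking(net: Network) -> list[dict]:
    """Gene nodes ranked by time-respecting downstream reach."""
    rows = []
    for fam, gene in net.family_genes.items():
        r = downstream_reach(net, gene)
        rows.append({"gene": gene, "family": fam, "n_res": r["n_res"],
                     "n_genes": r["n_genes"]})
    rows.sort(key=lambda d: (-d["n_genes"], -d["n_res"], d["gene"]))
    return rows


# ---------------------------------------------------------------------------
# the runnable pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, infer, evaluate, and (optionally) write all intermediates."""
    sim = config.sim
    log.info("pipeline start: seed=%d noiseless=%s", sim.seed, config.noiseless)
    truth, result = analyze_synthetic(sim, noiseless=config.noiseless,
                                      rules=config.rules)
    design = sim.design

    report = dict(result.report)
    report["seed"] = sim.seed
    report["noiseless"] = config.noiseless
    report["edge_recovery"] = precision_recall(truth.network, result.network)
    report["factor_fits"] = factor_fits(truth, result, design)
    report["cooperation"] = cooperation_summary(result, truth.genes)
    report["reach_ranking"] = reach_ranking(result.network)
    cocktail = {truth.family_genes[f] for f in config.rules.cocktail_families
                if f in truth.family_genes}
    non_cocktail = [r for r in report["reach_ranking"]
                    if r["gene"] not in cocktail]
    report["top_non_cocktail_node"] = non_cocktail[0]["gene"] if non_cocktail else None

    if config.out_dir and config.write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_peaks(truth.peaks, out / "peaks.bed")
        write_genes(truth.genes, out / "genes.tsv")
        result.atac_calls.to_csv(out / "atac_calls.tsv", sep="\t", index=False)
        result.gene_calls.to_csv(out / "gene_calls.tsv", sep="\t", index=False)
        result.hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        classes = result.peak_classes
        with open(out / "peak_classes.bed", "w") as fh:
            for p in truth.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                         f"{classes[p.name]}\n")
        write_network(result.network, out / "network.tsv",
                      out / "network.graphml")
        truth.to_json(out / "truth.json")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
    log.info("pipeline done: %d trans / %d cis edges",
             report["n_trans_edges"], report["n_cis_edges"])
    return report


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
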