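"""Random rule-engine input instances shared by unit and acceptance tests."""

import itertools

import numpy as np
import pandas as pd

from kineticnet.cdf import FactorConstraint
from kineticnet.io import Gene, Peak, PeakSet
from kineticnet.network import NetworkRules

TIMES = (0, 20, 40, 60, 120, 180, 240)
CALL_COLS = ["feature", "time_a", "time_b", "mean_a", "mean_b", "log2fc",
             "pvalue", "qvalue", "direction"]


def random_rule_instance(rng, n_re=30, n_genes=12, n_fams=4):
    fams = [f"F{i}" for i in range(n_fams)]
    functions = {f: rng.choice(["opener", "closer"]) for f in fams}
    family_genes = {f: f"tf_{f}" for f in fams}
    all_genes = [f"g{i}" for i in range(n_genes)] + list(family_genes.values())
    peaks = PeakSet([Peak("c", 2500 * i, 2500 * i + 400, f"re{i}")
                     for i in range(n_re)])
    genes = [Gene("c", int(rng.integers(0, n_re * 2500)),
                  0, g, "+") for g in []]  # placeholder, built below
    genes = []
    for j, g in enumerate(all_genes):
        start = int(rng.integers(0, n_re * 2500 + 30_000))
        genes.append(Gene("c", start, start + 8000, g, "+"))
    atac_rows, gene_rows = [], []
    for p in peaks:
        for a, b in itertools.combinations(TIMES, 2):
            r = rng.random()
            if r < 0.06:
                atac_rows.append((p.name, a, b, "up"))
            elif r < 0.12:
                atac_rows.append((p.name, a, b, "down"))
    for g in all_genes:
        for a, b in itertools.combinations(TIMES, 2):
            r = rng.random()
            if r < 0.08:
                gene_rows.append((g, a, b, "up"))
            elif r < 0.16:
                gene_rows.append((g, a, b, "down"))
    hit_pairs = [(p.name, f) for p in peaks for f in fams
                 if rng.random() < 0.3]
    expressed_frame = pd.DataFrame(
        rng.random((len(all_genes), len(TIMES))) < 0.8,
        index=all_genes, columns=list(TIMES))
    constraints = {}
    for f in fams:
        comps = [c for c in itertools.combinations(TIMES, 2)
                 if rng.random() < 0.4]
        max_d = int(rng.choice([2000, 5000, 10_000])) if rng.random() < 0.8 \
            else None
        constraints[f] = FactorConstraint(f, comps, max_d)
    rules = NetworkRules(
        cocktail_families=frozenset({"F0"}),
        cocktail_window_end=(("F0", 20),),
        binding_window_end=(("F1", 40),),
        min_edge_start=(("F2", 40),),
        function_overrides=())
    return (peaks, genes, functions, family_genes, calls_from(atac_rows),
            calls_from(gene_rows), hit_pairs, expressed_frame, constraints,
            rules)


def calls_from(rows):
    frame = pd.DataFrame(rows, columns=["feature", "time_a", "time_b",
                                        "direction"])
    frame["mean_a"] = frame["mean_b"] = 1.0
    frame["log2fc"] = np.where(frame["direction"] == "up", 1.0, -1.0)
    frame["pvalue"] = frame["qvalue"] = 0.0
    return frame[CALL_COLS[:3] + ["mean_a", "mean_b", "log2fc", "pvalue",
                                  "qvalue", "direction"]]


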