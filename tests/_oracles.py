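"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately re-derive each computation from its definition with plain
nested loops, sharing no code with the package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# PWM scoring


def brute_force_lattice_pvalues(lattice: np.ndarray, background: np.ndarray
                                ) -> dict[int, float]:
    """Exact P(score >= t) by enumerating every sequence of the PWM's length.

    ``lattice`` is the (w, 5) integer score matrix; only the first four
    columns (A, C, G, T) are used.
    """
    w = lattice.shape[0]
    totals = {}
    for seq in itertools.product(range(4), repeat=w):
        total = sum(lattice[i, b] for i, b in enumerate(seq))
        prob = 1.0
        for b in seq:
            prob *= background[b]
        totals[total] = totals.get(total, 0.0) + prob
    out = {}
    for t in totals:
        out[t] = sum(p for u, p in totals.items() if u >= t)
    return out


def brute_force_scan(sequence: str, bits: np.ndarray) -> list[float]:
    """Score every window of ``sequence`` directly with the (w, 5) bit matrix."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = bits.shape[0]
    scores = []
    for i in range(len(sequence) - w + 1):
        s = 0.0
        for j, base in enumerate(sequence[i:i + w]):
            s += bits[j, code.get(base, 4)]
        scores.append(s)
    return scores


# ---------------------------------------------------------------------------
# nearest distances


def brute_force_nearest(tss_list, summit_list):
    return [min(abs(t - s) for s in summit_list) for t in tss_list]


# ---------------------------------------------------------------------------
# network rules (independent nested-loop applicator)


def oracle_trans_edges(sig_atac_rows, peak_families, functions, family_genes,
                       gene_up_ends, gene_down_ends, expressed, cocktail,
                       cocktail_end, binding_end, min_start):
    """Re-derivation of the trans-edge rules with explicit loops.

    sig_atac_rows: list of (peak, t_a, t_b, direction) significant calls.
    gene_up_ends / gene_down_ends: gene -> sorted list of end times of
    significant activations / repressions.
    expressed: (gene, time) -> bool mapping.
    Returns a set of (family, peak, t_a, t_b, attribute).
    """
    binding = set()
    for peak, ta, tb, direction in sig_atac_rows:
        for fam in peak_families.get(peak, ()):  # rules 1-2
            func = functions.get(fam, "unassigned")
            if func == "unassigned":
                continue
            opens = func == "opener"
            attr = "binding" if (direction == "up") == opens else "dissociation"
            if ta < min_start.get(fam, 0):
                continue
            if attr != "binding":
                continue
            if fam in binding_end and tb > binding_end[fam]:
                continue
            gene = family_genes.get(fam)
            if gene is None or not expressed.get((gene, tb), False):
                continue
            exempt = fam in cocktail and tb <= cocktail_end.get(fam, 20)
            activated = any(v <= ta for v in gene_up_ends.get(gene, []))
            if exempt or activated:
                binding.add((fam, peak, ta, tb, "binding"))
    edges = set(binding)
    for peak, ta, tb, direction in sig_atac_rows:
        for fam in peak_families.get(peak, ()):
            func = functions.get(fam, "unassigned")
            if func == "unassigned":
                continue
            opens = func == "opener"
            attr = "binding" if (direction == "up") == opens else "dissociation"
            if attr != "dissociation" or ta < min_start.get(fam, 0):
                continue
            gene = family_genes.get(fam)
            if gene is None or not expressed.get((gene, ta), False):
                continue
            repressed = any(v <= ta for v in gene_down_ends.get(gene, []))
            prior = fam in cocktail and any(
                e[0] == fam and e[1] == peak and e[3] <= ta for e in binding)
            if repressed or prior:
                edges.add((fam, peak, ta, tb, "dissociation"))
    return edges


def oracle_cis_edges(trans_edges, peak_coords, peak_summits, gene_coords,
                     gene_tss, sig_gene_rows, functions, constraints,
                     max_gap=10_000, strict=False):
    """Re-derivation of the cis-edge rules with explicit loops.

    trans_edges: set of (family, peak, t_a, t_b, attribute).
    peak_coords/gene_coords: name -> (start, end) on one chromosome.
    sig_gene_rows: list of (gene, u, v, direction).
    constraints: family -> (set of comparisons, max_distance or None).
    Returns a set of (peak, gene, u, v, sign, frozenset(families)).
    """
    def gene_effect(func, attr):
        if func == "opener":
            return "up" if attr == "binding" else "down"
        return "down" if attr == "binding" else "up"

    out = {}
    for gene, u, v, direction in sig_gene_rows:
        gs, ge = gene_coords[gene]
        for peak, (ps, pe) in peak_coords.items():
            gap = max(gs - pe, ps - ge, 0)
            if gap > max_gap:
                continue
            fams = set()
            for (fam, pk, ta, tb, attr) in trans_edges:
                if pk != peak:
                    continue
                func = functions.get(fam, "unassigned")
                if func == "unassigned":
                    continue
                if gene_effect(func, attr) != direction:
                    continue
                if strict:
                    if (ta, tb) != (u, v):
                        continue
                elif not (ta <= v and u <= tb):
                    continue
                comps, max_d = constraints.get(fam, (set(), None))
                if max_d is None:
                    continue
                if abs(gene_tss[gene] - peak_summits[peak]) > max_d:
                    continue
                dyn_ok = any(
                    (uu, vv) in comps and g == gene and d == direction
                    for (g, uu, vv, d) in sig_gene_rows)
                if not dyn_ok:
                    continue
                fams.add(fam)
            if fams:
                sign = "activation" if direction == "up" else "repression"
                key = (peak, gene, u, v, sign)
                out.setdefault(key, set()).update(fams)
    return {k + (frozenset(f),) for k, f in out.items()}
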