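"""Synthetic adipogenesis-like time course with planted ground truth.

The generator lays out a single synthetic chromosome with genes spaced at
least 20 kb apart and a program of six TF families mirroring the early
adipogenic cascade: cocktail-activated opener families (AP-1-, CEBP- and
GR-like) acting from 0-20 min, a transcriptionally induced closer
("TWIST2-like") acting 20-60 min, a transcriptionally induced opener
("KLF-like") acting after 40 min, and a repressed opener ("SP-like") whose
promoter-proximal elements lose accessibility from 60 min as the factor pool
dissociates.  Each family's regulatory elements carry its embedded motif and
follow one of five kinetic accessibility classes; each target gene's
pause/body occupancy is generated from the two-compartment polymerase model
with planted per-interval fold changes in initiation and pause release.

Counts are negative binomial around depth-scaled planted means with
log-normal per-replicate library sizes — the standard count-data assumptions
of differential-accessibility machinery; the exact variance structure of the
emulated experiments is unknown, so this noise model is this package's own
choice.  All randomness flows
through one seeded generator; the same seed reproduces the TruthSet exactly.

The planted truth network is the closure of the documented inference rules
over the exact (noise-free) trajectories, so every planted edge is
recoverable in the noiseless limit by construction; the rule engine itself
is validated independently against a brute-force applicator in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import accessibility as acc
from .cdf import derive_constraints
from .compartment import RateParams, steady_state
from .io import Gene, Peak, PeakSet, SignalTrack
from .motifs import MotifModel, scan_peaks
from .network import Network, NetworkRules, build_network
from .proseq import expression_matrix

__all__ = [
    "TFFamily",
    "SimConfig",
    "TruthSet",
    "default_families",
    "make_pwm",
    "simulate_truth",
    "simulate_atac",
    "simulate_proseq",
    "make_tracks",
    "simulate_distance_benchmark",
]

CHROM = "chrS"
PEAK_WIDTH = 400
GENE_LENGTH = 8_000
GENE_SPACING = 20_000
PAUSE_SUMMIT_OFFSET = 40  # planted pause summit, bp downstream of the TSS
BODY_OFFSET = 250

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_pwm(consensus: str, p: float = 0.85) -> np.ndarray:
    """PWM with probability ``p`` on the consensus base, rest uniform."""
    lut = {b: i for i, b in enumerate("ACGT")}
    w = len(consensus)
    pwm = np.full((w, 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        pwm[i, lut[b]] = p
    return pwm


@dataclass
class TFFamily:
    """One planted TF family: motif, function, regulation mode, and program."""

    name: str
    consensus: str
    function: str  # opener | closer
    regulation: str  # cocktail | transcriptional
    re_levels_linked: tuple  # relative accessibility of linked REs per time point
    re_levels_unlinked: tuple
    n_unlinked: int  # dynamic REs with no nearby gene (bound, no target)
    target_distance_bp: tuple  # (lo, hi) summit-to-TSS distance for linked REs
    n_targets: int
    target_schedule: dict  # interval -> (f_init, f_rel) for target genes
    gene_schedule: dict  # interval -> (f_init, f_rel) for the family's own gene
    # family genes get a fixed (not sampled) baseline initiation rate: the
    # planted program requires them to stay above the expression floor at
    # the time points where the family acts
    gene_k_init: float = 15.0
    attenuated_fraction: float = 0.0
    attenuation_interval: tuple = (60, 120)

    @property
    def gene_name(self) -> str:
        return f"{self.name}_gene"

    def pwm(self) -> MotifModel:
        return MotifModel(self.name, make_pwm(self.consensus), function=self.function)


def default_families() -> list[TFFamily]:
    """The default planted program (see the module docstring)."""
    imm = (1, 3, 3, 3, 3, 3, 3)        # immediate increase
    trans_up = (1, 3, 3, 1, 1, 1, 1)   # transient increase (GR-like)
    grad_up = (1, 1, 1, 3, 3, 3, 3)    # gradual increase (KLF-like)
    grad_dn = (3, 3, 1, 1, 1, 1, 1)    # gradual decrease (TWIST-like)
    trans_dn = (3, 3, 1, 1, 1, 3, 3)   # transient decrease
    late_dn = (3, 3, 3, 3, 1, 1, 1)    # gradual decrease, late (SP-like)
    act_early = {(0, 20): (2.0, 1.0)}
    return [
        TFFamily("AP1", "TGACTCAT", "opener", "cocktail", imm, imm, 6,
                 (600, 2400), 6, dict(act_early), dict(act_early),
                 attenuated_fraction=0.6),
        TFFamily("CEBP", "TTGCGCAA", "opener", "cocktail", imm, imm, 5,
                 (600, 2400), 5, dict(act_early), dict(act_early),
                 attenuated_fraction=0.6),
        TFFamily("GR", "AGAACAGT", "opener", "cocktail", trans_up, trans_up, 6,
                 (600, 2400), 6, {(0, 20): (2.0, 1.5)}, {(0, 20): (0.6, 1.0)},
                 gene_k_init=25.0, attenuated_fraction=0.8),
        TFFamily("KLF", "GGGTGTGG", "opener", "transcriptional", grad_up, grad_up,
                 4, (600, 2400), 6, {(40, 60): (2.0, 1.0)}, dict(act_early)),
        TFFamily("TWIST", "CCAGATGT", "closer", "transcriptional", grad_dn,
                 trans_dn, 4, (600, 2400), 7, {(40, 60): (0.4, 1.0)},
                 {(0, 20): (3.0, 1.0), (60, 120): (1 / 3, 1.0)}),
        TFFamily("SP", "GGGGCGGG", "opener", "transcriptional", late_dn, late_dn,
                 0, (60, 300), 10, {(60, 120): (0.5, 1.0)},
                 {(40, 60): (0.4, 1.0)}, gene_k_init=30.0),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic time course."""

    time_points: tuple = (0, 20, 40, 60, 120, 180, 240)
    n_replicates: int = 3
    # 74 planted dynamic REs out of 560 peaks = 13% dynamic, the fraction
    # of significantly changing peaks the source time course showed
    n_res: int = 560
    n_genes: int = 120
    tf_families: list = field(default_factory=default_families)
    dispersion: float = 0.05  # shared NB overdispersion
    depth: float = 110_000.0  # mean ATAC library size (counts in peaks)
    proseq_scale: float = 60.0  # PRO-seq reads per polymerase
    library_sigma: float = 0.08  # log-normal spread of replicate library sizes
    n_shared_ap1_gr: int = 6  # REs carrying both AP-1 and GR motifs
    q_threshold: float = 0.05
    n_permutations: int = 300
    seed: int = 0

    def __post_init__(self):
        tps = tuple(self.time_points)
        if tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("time points must be strictly increasing from 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for fam in self.tf_families:
            for lv in (fam.re_levels_linked, fam.re_levels_unlinked):
                if len(lv) != len(tps):
                    raise ValueError(
                        f"family {fam.name}: levels not defined at every time point")

    @property
    def design(self) -> pd.DataFrame:
        return acc.make_design(self.time_points, self.n_replicates)


@dataclass
class TruthSet:
    """Everything planted by :func:`simulate_truth`, plus the rule closure."""

    seed: int
    time_points: tuple
    genes: list
    peaks: PeakSet
    genome: dict
    gene_roles: dict  # gene -> role string
    peak_meta: pd.DataFrame  # family, class, linked gene, levels per peak
    peak_levels: pd.DataFrame  # peak x time relative accessibility
    peak_strength: pd.Series
    gene_base_params: dict  # gene -> RateParams at t0
    gene_schedules: dict  # gene -> {interval: (f_init, f_rel)}
    pause_occupancy: pd.DataFrame  # gene x time, polymerases in the pause
    body_density: pd.DataFrame  # gene x time, polymerases/bp
    family_genes: dict
    functions: dict
    motifs: list
    hits: pd.DataFrame
    exact_atac_calls: pd.DataFrame
    exact_gene_calls: pd.DataFrame
    expressed: pd.DataFrame
    constraints: dict
    network: Network
    attenuated_genes: set

    @property
    def peak_class(self) -> dict:
        return dict(zip(self.peak_meta.index, self.peak_meta["kinetic_class"]))

    def to_json(self, path, include_genome: bool = False) -> None:
        payload = {
            "seed": self.seed,
            "time_points": list(self.time_points),
            "gene_roles": self.gene_roles,
            "peak_class": self.peak_class,
            "attenuated_genes": sorted(self.attenuated_genes),
            "family_genes": self.family_genes,
            "functions": self.functions,
            "constraints": {f: c.to_dict() for f, c in self.constraints.items()},
            "gene_base_params": {
                g: {"k_init": p.k_init, "k_pre": p.k_pre, "k_rel": p.k_rel,
                    "k_elong": p.k_elong, "L": p.L}
                for g, p in self.gene_base_params.items()},
            "gene_schedules": {
                g: {f"{a}-{b}": list(fc) for (a, b), fc in sched.items()}
                for g, sched in self.gene_schedules.items()},
            "trans_edges": [list(e.key) + [e.attenuated]
                            for e in self.network.trans_edges],
            "cis_edges": [[e.re_id, e.gene, e.t_a, e.t_b, e.sign,
                           sorted(e.families), e.attenuated]
                          for e in self.network.cis_edges],
        }
        if include_genome:
            payload["genome"] = self.genome
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _exact_calls(levels: pd.DataFrame, time_points,
                 min_abs_log2fc: float = acc.DEFAULT_LFC_FLOOR) -> pd.DataFrame:
    """Noise-free differential calls: the planted ratio clears the same
    effect-size floor the analysis pipeline applies."""
    rows = []
    times = list(time_points)
    for i, ta in enumerate(times):
        for tb in times[i + 1:]:
            a = levels[ta].to_numpy(dtype=float)
            b = levels[tb].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(a > 0, b / np.maximum(a, 1e-300), np.inf)
            changed = np.abs(np.log2(ratio)) >= min_abs_log2fc
            direction = np.where(changed, np.where(ratio > 1, "up", "down"), "none")
            for feat, ma, mb, lfc, d in zip(levels.index, a, b,
                                            np.log2(np.maximum(ratio, 1e-300)),
                                            direction):
                rows.append((feat, ta, tb, ma, mb, lfc,
                             0.0 if d != "none" else 1.0,
                             0.0 if d != "none" else 1.0, d))
    return pd.DataFrame(rows, columns=["feature", "time_a", "time_b", "mean_a",
                                       "mean_b", "log2fc", "pvalue", "qvalue",
                                       "direction"])


def _gene_occupancy(base: RateParams, schedule: dict, time_points
                    ) -> tuple[list, list]:
    """Steady-state (P, b) at each time point after cumulative fold changes."""
    P, b = [], []
    params = base
    applied: set = set()
    for t in time_points:
        for (a, v), (fi, fr) in sorted(schedule.items()):
            if v <= t and (a, v) not in applied:
                params = params.scaled(fi, fr)
                applied.add((a, v))
        occ = steady_state(params)
        P.append(occ.P)
        b.append(occ.b)
    return P, b


def simulate_truth(config: SimConfig) -> TruthSet:
    """Generate genes, motif-bearing peaks, kinetics and the truth network."""
    rng = np.random.default_rng(config.seed)
    times = tuple(config.time_points)
    families = config.tf_families
    fam_by_name = {f.name: f for f in families}

    n_named_genes = (len(families)
                     + sum(f.n_targets for f in families) + config.n_shared_ap1_gr)
    if n_named_genes > config.n_genes:
        raise ValueError(
            f"infeasible config: {n_named_genes} planted genes > "
            f"n_genes={config.n_genes}")

    # ---- gene roles, shuffled onto chromosome slots ----------------------
    roles: list[tuple[str, str]] = [("family", f.name) for f in families]
    for f in families:
        roles += [("target", f.name)] * f.n_targets
    roles += [("target", "SHARED")] * config.n_shared_ap1_gr
    roles += [("unchanged", "")] * (config.n_genes - len(roles))
    rng.shuffle(roles)

    genes: list[Gene] = []
    gene_roles: dict[str, str] = {}
    role_members: dict[str, list[str]] = {}
    for i, (kind, fam) in enumerate(roles):
        start = (i + 1) * GENE_SPACING
        strand = "-" if i % 5 == 4 else "+"
        if kind == "family":
            name = fam_by_name[fam].gene_name
        else:
            name = f"g{i:03d}"
        genes.append(Gene(CHROM, start, start + GENE_LENGTH, name, strand))
        gene_roles[name] = f"{kind}:{fam}" if fam else "unchanged"
        role_members.setdefault(f"{kind}:{fam}" if fam else "unchanged",
                                []).append(name)
    gene_by_name = {g.name: g for g in genes}

    # ---- gene kinetics ---------------------------------------------------
    gene_base_params: dict[str, RateParams] = {}
    gene_schedules: dict[str, dict] = {}
    attenuated_genes: set[str] = set()

    L_body = GENE_LENGTH - PAUSE_SUMMIT_OFFSET - BODY_OFFSET

    for g in genes:
        role = gene_roles[g.name]
        schedule: dict = {}
        if role.startswith("family:"):
            fam = fam_by_name[role.split(":")[1]]
            schedule = dict(fam.gene_schedule)
            k_init = fam.gene_k_init  # fixed: must stay above the floor
        elif role.startswith("target:"):
            tag = role.split(":")[1]
            fam = fam_by_name.get(tag)
            schedule = dict(fam.target_schedule) if fam else {(0, 20): (2.0, 1.0)}
            k_init = float(10.0 * rng.lognormal(0.0, 0.35))
        else:
            k_init = float(10.0 * rng.lognormal(0.0, 0.35))
        gene_base_params[g.name] = RateParams(k_init, 0.2, 2.0, 2500.0, L_body)
        gene_schedules[g.name] = schedule

    # attenuation: a later inverse fold for a planted fraction of targets
    for f in families + [None]:
        tag = f.name if f else "SHARED"
        frac = f.attenuated_fraction if f else 0.6
        interval = f.attenuation_interval if f else (60, 120)
        members = role_members.get(f"target:{tag}", [])
        n_att = int(round(frac * len(members)))
        for name in rng.permutation(members)[:n_att]:
            sched = gene_schedules[name]
            if interval in sched:
                continue
            fi = fr = 1.0
            for (_a, _v), (i0, r0) in sched.items():
                fi *= i0
                fr *= r0
            sched[interval] = (1.0 / fi, 1.0 / fr)
            attenuated_genes.add(name)

    pause_occ = {}
    body_den = {}
    for g in genes:
        P, b = _gene_occupancy(gene_base_params[g.name], gene_schedules[g.name],
                               times)
        pause_occ[g.name] = P
        body_den[g.name] = b
    pause_occupancy = pd.DataFrame(pause_occ, index=list(times)).T
    body_density = pd.DataFrame(body_den, index=list(times)).T

    # ---- RE layout -------------------------------------------------------
    # planted peaks: (summit, family tag(s), class levels, linked gene)
    planted: list[dict] = []

    def upstream_summit(gene: Gene, lo: int, hi: int) -> int:
        d = int(rng.integers(lo, hi + 1))
        return gene.tss - d if gene.strand == "+" else gene.tss + d

    for f in families:
        targets = role_members.get(f"target:{f.name}", [])
        linked_genes = targets + [f2.gene_name for f2 in families
                                  if _linked_family_gene(f2) == f.name]
        for name in linked_genes:
            g = gene_by_name[name]
            planted.append({"summit": upstream_summit(g, *f.target_distance_bp),
                            "families": (f.name,), "levels": f.re_levels_linked,
                            "linked_gene": name})
    # shared AP-1 + GR REs near SHARED target genes
    imm = fam_by_name["AP1"].re_levels_linked
    for name in role_members.get("target:SHARED", []):
        g = gene_by_name[name]
        planted.append({"summit": upstream_summit(g, 600, 2400),
                        "families": ("AP1", "GR"), "levels": imm,
                        "linked_gene": name})
    # unlinked dynamic REs in a gene-free tail region
    tail_start = (config.n_genes + 3) * GENE_SPACING
    k = 0
    for f in families:
        for _ in range(f.n_unlinked):
            planted.append({"summit": tail_start + k * 25_000
                            + int(rng.integers(-2000, 2001)),
                            "families": (f.name,), "levels": f.re_levels_unlinked,
                            "linked_gene": None})
            k += 1
    genome_len = tail_start + (k + 2) * 25_000

    # background nondynamic peaks, kept clear of planted summits
    flat = tuple([2] * len(times))
    taken = sorted(p["summit"] for p in planted)
    n_background = config.n_res - len(planted)
    if n_background < 0:
        raise ValueError(
            f"infeasible config: {len(planted)} planted REs > n_res={config.n_res}")
    placed = 0
    while placed < n_background:
        pos = int(rng.integers(1000, genome_len - 1000))
        j = np.searchsorted(taken, pos)
        near = [taken[max(j - 1, 0)], taken[min(j, len(taken) - 1)]]
        if min(abs(pos - q) for q in near) < 1500:
            continue
        planted.append({"summit": pos, "families": (), "levels": flat,
                        "linked_gene": None})
        taken.insert(int(np.searchsorted(taken, pos)), pos)
        placed += 1

    planted.sort(key=lambda d: d["summit"])
    peaks = []
    meta_rows = []
    levels_rows = {}
    for i, d in enumerate(planted):
        name = f"re{i:04d}"
        start = d["summit"] - PEAK_WIDTH // 2
        peaks.append(Peak(CHROM, start, start + PEAK_WIDTH, name,
                          summit_offset=PEAK_WIDTH // 2))
        meta_rows.append((name, ",".join(d["families"]),
                          _class_of_levels(d["levels"], times),
                          d["linked_gene"] or ""))
        levels_rows[name] = list(d["levels"])
    peak_set = PeakSet(peaks)
    peak_meta = pd.DataFrame(
        meta_rows, columns=["peak", "families", "kinetic_class", "linked_gene"]
    ).set_index("peak")
    peak_levels = pd.DataFrame(levels_rows, index=list(times)).T
    strengths = pd.Series(100.0 * rng.lognormal(0.0, 0.25, size=len(peak_set)),
                          index=peak_set.names, name="strength")

    # ---- genome sequence with embedded motifs ----------------------------
    seq = rng.integers(0, 4, size=genome_len)
    lut = {b: i for i, b in enumerate("ACGT")}
    for d in planted:
        fams = d["families"]
        for fi, fam in enumerate(fams):
            cons = fam_by_name[fam].consensus
            offset = d["summit"] - len(cons) // 2 + (fi * 14 - 7 * (len(fams) - 1))
            enc = [lut[b] for b in cons]
            if rng.random() < 0.5:  # embed on the minus strand half the time
                enc = [3 - c for c in enc[::-1]]
            seq[offset:offset + len(cons)] = enc
    genome = {CHROM: _BASES[seq].tobytes().decode("ascii")}

    # ---- scans, exact calls, closure -------------------------------------
    motifs = [f.pwm() for f in families]
    hits = scan_peaks(peak_set, genome, motifs)

    exact_atac = _exact_calls(peak_levels, times)
    exact_gene = _exact_calls(body_density, times)
    expressed = expression_matrix(body_density)

    functions = {f.name: f.function for f in families}
    family_genes = {f.name: f.gene_name for f in families}
    rules = NetworkRules()
    resolved = dict(functions)
    resolved.update(rules.overrides)
    constraints = derive_constraints(
        peak_set, hits, exact_atac, exact_gene, genes, resolved,
        seed=config.seed, n_permutations=config.n_permutations)
    net = build_network(peak_set, genes, exact_atac, hits, functions,
                        family_genes, exact_gene, expressed, constraints, rules)

    return TruthSet(
        seed=config.seed, time_points=times, genes=genes, peaks=peak_set,
        genome=genome, gene_roles=gene_roles, peak_meta=peak_meta,
        peak_levels=peak_levels, peak_strength=strengths,
        gene_base_params=gene_base_params, gene_schedules=gene_schedules,
        pause_occupancy=pause_occupancy, body_density=body_density,
        family_genes=family_genes, functions=functions, motifs=motifs,
        hits=hits, exact_atac_calls=exact_atac, exact_gene_calls=exact_gene,
        expressed=expressed, constraints=constraints, network=net,
        attenuated_genes=attenuated_genes)


def _linked_family_gene(fam: TFFamily) -> str | None:
    """Which upstream family's RE activates this family's own gene."""
    return {"TWIST": "AP1", "KLF": "CEBP", "SP": "TWIST",
            "AP1": None, "CEBP": None, "GR": None}.get(fam.name)


def _class_of_levels(levels, times) -> str:
    lv = np.asarray(levels, dtype=float)
    if np.all(lv == lv[0]):
        return "nondynamic"
    first_change = int(np.flatnonzero(lv != lv[0])[0])
    up = lv[first_change] > lv[0]
    returns = abs(lv[-1] - lv[0]) <= 0.5 * abs(
        (lv.max() if up else lv.min()) - lv[0])
    reversal = ((np.diff(lv) < 0).any() if up else (np.diff(lv) > 0).any())
    if up:
        if reversal and returns:
            return "transient_increase"
        return "immediate_increase" if first_change == 1 else "gradual_increase"
    return "transient_decrease" if (reversal and returns) else "gradual_decrease"


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             noiseless: bool) -> np.ndarray:
    if noiseless:
        return mean.astype(float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def simulate_atac(truth: TruthSet, config: SimConfig,
                  rng: np.random.Generator | None = None,
                  noiseless: bool = False) -> pd.DataFrame:
    """Replicated peak x sample ATAC count matrix (NB around planted means)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    design = config.design
    levels = truth.peak_levels.to_numpy(dtype=float)
    strength = truth.peak_strength.to_numpy()[:, None]
    base = levels * strength  # peak x time
    scale = config.depth / base.sum(axis=0).mean()
    times = list(truth.time_points)
    cols = {}
    for sample, row in design.iterrows():
        lib = 1.0 if noiseless else rng.lognormal(0.0, config.library_sigma)
        mean = base[:, times.index(row["time"])] * scale * lib
        cols[sample] = _nb_draw(rng, mean, config.dispersion, noiseless)
    return pd.DataFrame(cols, index=truth.peak_levels.index)


def simulate_proseq(truth: TruthSet, config: SimConfig,
                    rng: np.random.Generator | None = None,
                    noiseless: bool = False
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(pause_counts, body_counts) gene x sample matrices.

    Planted means are proportional to the compartment-model steady-state
    occupancies at each time point: pause reads ~ scale * P, body reads ~
    scale * b * L.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    design = config.design
    times = list(truth.time_points)
    P = truth.pause_occupancy.to_numpy(dtype=float)
    b = truth.body_density.to_numpy(dtype=float)
    L = np.array([truth.gene_base_params[g].L
                  for g in truth.pause_occupancy.index])[:, None]
    pause_cols, body_cols = {}, {}
    for sample, row in design.iterrows():
        lib = 1.0 if noiseless else rng.lognormal(0.0, config.library_sigma)
        ti = times.index(row["time"])
        pause_cols[sample] = _nb_draw(
            rng, config.proseq_scale * P[:, ti] * lib, config.dispersion, noiseless)
        body_cols[sample] = _nb_draw(
            rng, config.proseq_scale * b[:, ti] * L[:, 0] * lib,
            config.dispersion, noiseless)
    idx = truth.pause_occupancy.index
    return (pd.DataFrame(pause_cols, index=idx), pd.DataFrame(body_cols, index=idx))


def make_tracks(truth: TruthSet, time_point: int, scale: float = 100.0,
                divergent_fraction: float = 0.4) -> SignalTrack:
    """Noise-free strand-specific signal for one time point.

    Each gene gets a triangular pause peak of total area ``scale * P`` over
    the 50-bp window around the planted pause summit (unique maximum at the
    summit), uniform body signal at ``scale * b``, and a divergent antisense
    peak upstream of the TSS at ``divergent_fraction`` of the mean pause
    density.
    """
    track = SignalTrack()
    offsets = np.arange(50)
    weights = 26.0 - np.abs(offsets - 25)  # unique max at offset 25
    weights /= weights.sum()
    for g in truth.genes:
        P = float(truth.pause_occupancy.at[g.name, time_point])
        b = float(truth.body_density.at[g.name, time_point])
        pause_vals = scale * P * weights  # per-bp, sums to scale * P
        body_density_v = scale * b
        anti = divergent_fraction * scale * P / 50.0
        if g.strand == "+":
            s0 = g.tss + PAUSE_SUMMIT_OFFSET - 25
            for o, v in zip(offsets, pause_vals):
                track.add(g.chrom, s0 + int(o), s0 + int(o) + 1, v, "+")
            track.add(g.chrom, s0 + 50 + BODY_OFFSET - 25, g.end, body_density_v, "+")
            if anti > 0:
                track.add(g.chrom, g.tss - 160, g.tss - 110, anti, "-")
        else:
            s1 = g.tss - PAUSE_SUMMIT_OFFSET + 25  # mirror image
            for o, v in zip(offsets, pause_vals):
                track.add(g.chrom, s1 - int(o) - 1, s1 - int(o), v, "-")
            track.add(g.chrom, g.start, s1 - 50 - BODY_OFFSET + 25, body_density_v, "-")
            if anti > 0:
                track.add(g.chrom, g.tss + 110, g.tss + 160, anti, "+")
    return track


def simulate_distance_benchmark(n_dynamic: int = 400, n_unchanged: int = 400,
                                actionable_bp: int = 5000,
                                far_bp: int = 200_000, n_factor_peaks: int = 40,
                                seed: int = 0) -> dict:
    """Planted actionable-distance benchmark for the CDF plateau estimator.

    Factor summits are spaced 500 kb apart; dynamic gene TSSs are uniform
    within ``actionable_bp`` of a random summit, unchanged gene TSSs uniform
    within ``far_bp``.  Returns summits and both TSS arrays.
    """
    rng = np.random.default_rng(seed)
    summits = (np.arange(n_factor_peaks) + 1) * 500_000
    dyn_anchor = summits[rng.integers(0, n_factor_peaks, size=n_dynamic)]
    unch_anchor = summits[rng.integers(0, n_factor_peaks, size=n_unchanged)]
    sign_d = rng.choice([-1, 1], size=n_dynamic)
    sign_u = rng.choice([-1, 1], size=n_unchanged)
    tss_dynamic = dyn_anchor + sign_d * rng.integers(0, actionable_bp + 1,
                                                     size=n_dynamic)
    tss_unchanged = unch_anchor + sign_u * rng.integers(0, far_bp + 1,
                                                        size=n_unchanged)
    return {"summits": summits, "tss_dynamic": tss_dynamic,
            "tss_unchanged": tss_unchanged}
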