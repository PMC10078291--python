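"""Two-compartment model of promoter-proximal RNA polymerase II kinetics.

The gene unit is split into a pause compartment and a gene-body compartment.
Polymerase flows in by initiation/recruitment (``k_init``, polymerases/min),
leaves the pause either by premature termination (``k_pre``, /min) or by pause
release into the body (``k_rel``, /min), and exits the body by elongation at
``k_elong`` bp/min over a body of length ``L`` bp:

    dP/dt = k_init - (k_pre + k_rel) * P
    db/dt = k_rel * P / L - (k_elong / L) * b        (b = body density, pol/bp)

At steady state ``P* = k_init / (k_pre + k_rel)`` and
``b* = k_rel * P* / k_elong``; the mean pause residency time is
``tau = 1 / (k_pre + k_rel)``.  Between two measured time points the model is
refit by holding ``k_pre`` and ``k_elong`` fixed and solving for multiplicative
fold changes ``f_init`` (in ``k_init``) and ``f_rel`` (in ``k_rel``) that map
the first occupancy snapshot onto the second.  Because the two snapshots only
constrain ``k_init/(k_pre+k_rel)`` and ``k_rel/k_elong``, a whole manifold of
base rate sets is consistent with the first snapshot; the fit scans a grid of
base sets and reports the distribution of fold changes across it.  ``f_rel``
is identified exactly by the two snapshots regardless of ``k_pre``; the spread
in ``f_init`` across the grid vanishes as ``k_pre/k_rel -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateParams",
    "Occupancy",
    "FoldChanges",
    "PAUSE_REGION_BP",
    "steady_state",
    "residency_seconds",
    "integrate_occupancy",
    "default_base_grid",
    "consistent_base_grid",
    "fit_fold_changes",
    "simulate_profile",
    "TwoCompartmentModel",
    "FoldChangeResults",
]

PAUSE_REGION_BP = 50
CONSENSUS_ELONGATION_BP_PER_MIN = 2500.0


@dataclass(frozen=True)
class RateParams:
    """Rate constants; time unit is minutes, length unit is bp."""

    k_init: float  # polymerases/min entering the pause compartment
    k_pre: float  # /min premature termination out of the pause
    k_rel: float  # /min pause release into the body
    k_elong: float  # bp/min elongation speed
    L: float = 20_000.0  # gene-body length, bp

    def __post_init__(self):
        for name in ("k_init", "k_rel", "k_elong", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_pre < 0:
            raise ValueError("k_pre must be non-negative")

    def scaled(self, f_init: float = 1.0, f_rel: float = 1.0) -> "RateParams":
        """Apply fold changes to initiation and pause release; k_pre, k_elong fixed."""
        return RateParams(self.k_init * f_init, self.k_pre, self.k_rel * f_rel,
                          self.k_elong, self.L)


@dataclass(frozen=True)
class Occupancy:
    """Polymerase occupancy: pause count P and body density b (pol/bp)."""

    P: float
    b: float

    def __post_init__(self):
        if self.P < 0 or self.b < 0:
            raise ValueError("occupancies must be non-negative")


@dataclass(frozen=True)
class FoldChanges:
    f_init: float
    f_rel: float

    def __post_init__(self):
        if self.f_init <= 0 or self.f_rel <= 0:
            raise ValueError("fold changes must be positive")


def steady_state(params: RateParams) -> Occupancy:
    """Closed-form steady-state occupancy."""
    P = params.k_init / (params.k_pre + params.k_rel)
    b = params.k_rel * P / params.k_elong
    return Occupancy(P=P, b=b)


def residency_seconds(params: RateParams) -> float:
    """Mean pause residency time tau = 1/(k_pre + k_rel), in seconds."""
    return 60.0 / (params.k_pre + params.k_rel)


def integrate_occupancy(params: RateParams, occ0: Occupancy, t_minutes: float,
                        rtol: float = 1e-10, atol: float = 1e-12) -> Occupancy:
    """Integrate the two ODEs from ``occ0`` for ``t_minutes``."""
    from scipy.integrate import solve_ivp

    k_i, k_p, k_r, k_e, L = (params.k_init, params.k_pre, params.k_rel,
                             params.k_elong, params.L)

    def rhs(_t, y):
        P, b = y
        return [k_i - (k_p + k_r) * P, k_r * P / L - (k_e / L) * b]

    sol = solve_ivp(rhs, (0.0, t_minutes), [occ0.P, occ0.b], rtol=rtol, atol=atol,
                    method="LSODA")
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Occupancy(P=float(sol.y[0, -1]), b=float(sol.y[1, -1]))


def default_base_grid(k_init_range=(0.5, 50.0), k_pre_range=(0.02, 2.0),
                      k_rel_range=(0.2, 20.0), k_elong_range=(600.0, 6000.0),
                      points_per_decade: int = 25, n_elong: int = 10,
                      include_zero_k_pre: bool = False) -> pd.DataFrame:
    """Base-parameter grid: 25 log-spaced values/decade over two decades for
    ``k_init``, ``k_pre``, ``k_rel``; ``n_elong`` linear values for ``k_elong``."""

    def logspan(lo, hi):
        n = int(round(points_per_decade * np.log10(hi / lo))) + 1
        return np.geomspace(lo, hi, n)

    k_i = logspan(*k_init_range)
    k_p = logspan(*k_pre_range)
    if include_zero_k_pre:
        k_p = np.concatenate([[0.0], k_p])
    k_r = logspan(*k_rel_range)
    k_e = np.linspace(*k_elong_range, n_elong)
    grid = np.array(np.meshgrid(k_i, k_p, k_r, k_e, indexing="ij")).reshape(4, -1).T
    return pd.DataFrame(grid, columns=["k_init", "k_pre", "k_rel", "k_elong"])


def consistent_base_grid(occ: Occupancy, k_rel_values=None,
                         k_pre_ratios=(0.0,),
                         k_elong_range=(600.0, 6000.0)) -> pd.DataFrame:
    """Base sets exactly consistent with one occupancy snapshot.

    The snapshot pins only two rate combinations — ``k_init/(k_pre+k_rel)``
    and ``k_rel/k_elong`` — so the consistent sets form a two-parameter
    manifold indexed here by ``k_rel`` and the ratio ``k_pre/k_rel``.  Rows
    whose implied ``k_elong`` falls outside ``k_elong_range`` are dropped.
    """
    if k_rel_values is None:
        k_rel_values = np.geomspace(0.2, 20.0, 41)
    rows = []
    for k_rel in np.asarray(k_rel_values, dtype=float):
        k_elong = k_rel * occ.P / occ.b
        if not k_elong_range[0] <= k_elong <= k_elong_range[1]:
            continue
        for r in k_pre_ratios:
            k_pre = r * k_rel
            rows.append((occ.P * (k_pre + k_rel), k_pre, k_rel, k_elong))
    if not rows:
        raise ValueError("no consistent base set with k_elong in range")
    return pd.DataFrame(rows, columns=["k_init", "k_pre", "k_rel", "k_elong"])


def fit_fold_changes(occ_t1: Occupancy, occ_t2: Occupancy,
                     grid: pd.DataFrame | None = None, tol: float = 0.01,
                     L: float = 20_000.0) -> "FoldChangeResults":
    """Grid fit of (f_init, f_rel) between two steady-state snapshots.

    Every base set on the grid whose steady state reproduces ``occ_t1`` within
    ``tol`` (relative, on both P and b) is retained; for each, the unique
    (f_init, f_rel) mapping it onto ``occ_t2`` with ``k_pre`` and ``k_elong``
    held fixed is solved in closed form:

        f_rel  = b2 * k_elong / (k_rel * P2)
        f_init = P2 * (k_pre + f_rel * k_rel) / k_init

    The point estimate is taken at the base set with the smallest ``occ_t1``
    residual, ties broken toward ``k_elong`` nearest the 2500 bp/min consensus
    elongation rate, then toward smaller ``k_pre``.
    """
    if occ_t1.P <= 0 or occ_t1.b <= 0 or occ_t2.P <= 0 or occ_t2.b <= 0:
        raise ValueError("both occupancy snapshots must be positive")
    if grid is None:
        grid = default_base_grid()
    if len(grid) == 0:
        raise ValueError("empty base grid")

    k_i = grid["k_init"].to_numpy(float)
    k_p = grid["k_pre"].to_numpy(float)
    k_r = grid["k_rel"].to_numpy(float)
    k_e = grid["k_elong"].to_numpy(float)

    P_pred = k_i / (k_p + k_r)
    b_pred = k_r * P_pred / k_e
    resid = np.maximum(np.abs(P_pred / occ_t1.P - 1.0), np.abs(b_pred / occ_t1.b - 1.0))
    keep = resid <= tol
    if not np.any(keep):
        raise ValueError(
            "no base parameter set on the grid is consistent with occ_t1 within "
            f"tol={tol} (best residual {resid.min():.3g}); widen the grid or tolerance"
        )

    sub = grid.loc[keep].reset_index(drop=True).copy()
    k_i, k_p, k_r, k_e = (sub[c].to_numpy(float)
                          for c in ("k_init", "k_pre", "k_rel", "k_elong"))
    f_rel = occ_t2.b * k_e / (k_r * occ_t2.P)
    f_init = occ_t2.P * (k_p + f_rel * k_r) / k_i
    sub["f_rel"] = f_rel
    sub["f_init"] = f_init
    sub["residual"] = resid[keep]

    order = np.lexsort((k_p, np.abs(k_e - CONSENSUS_ELONGATION_BP_PER_MIN),
                        sub["residual"].to_numpy()))
    best_idx = int(order[0])
    best_row = sub.iloc[best_idx]
    base = RateParams(best_row["k_init"], best_row["k_pre"], best_row["k_rel"],
                      best_row["k_elong"], L)
    return FoldChangeResults(
        fold_changes=FoldChanges(float(best_row["f_init"]), float(best_row["f_rel"])),
        base_params=base, distribution=sub, occ_t1=occ_t1, occ_t2=occ_t2, tol=tol,
    )


def simulate_profile(params: RateParams, pause_summit: int = 40,
                     pause_region_bp: int = PAUSE_REGION_BP, n_bp: int | None = None,
                     smooth_sigma_bp: float = 0.0) -> np.ndarray:
    """Simulated per-bp Pol II density along a gene (position 0 = TSS).

    The pause region ``[summit - 25, summit + 25)`` carries density ``P*/50``
    per bp; downstream positions carry the body density ``b*``.  With no
    smoothing the area under the pause region equals ``P*`` exactly.
    """
    occ = steady_state(params)
    if n_bp is None:
        n_bp = int(params.L)
    prof = np.zeros(n_bp)
    a = max(0, pause_summit - pause_region_bp // 2)
    b = min(n_bp, pause_summit + pause_region_bp - pause_region_bp // 2)
    pause = np.zeros(n_bp)
    pause[a:b] = occ.P / pause_region_bp
    if smooth_sigma_bp > 0:
        from scipy.ndimage import gaussian_filter1d

        pause = gaussian_filter1d(pause, smooth_sigma_bp, mode="constant")
    prof += pause
    prof[b:] += occ.b
    return prof


class TwoCompartmentModel:
    """statsmodels-style wrapper: occupancy snapshots in, fold-change fit out.

    Parameters
    ----------
    occ_t1, occ_t2 : Occupancy
        Pause-region polymerase count P and body density b (pol/bp) at the
        two time points, measured from PRO-seq read densities.
    L : float
        Gene-body length in bp (enters only via the profile simulation).
    """

    def __init__(self, occ_t1: Occupancy, occ_t2: Occupancy, L: float = 20_000.0):
        self.occ_t1 = occ_t1
        self.occ_t2 = occ_t2
        self.L = L

    @classmethod
    def from_densities(cls, pause_density_t1: float, body_density_t1: float,
                       pause_density_t2: float, body_density_t2: float,
                       pause_region_bp: int = PAUSE_REGION_BP, L: float = 20_000.0):
        """Build from per-bp densities; pause count P = pause density * 50 bp."""
        return cls(Occupancy(pause_density_t1 * pause_region_bp, body_density_t1),
                   Occupancy(pause_density_t2 * pause_region_bp, body_density_t2), L)

    def fit(self, grid: pd.DataFrame | None = None, tol: float = 0.01) -> "FoldChangeResults":
        return fit_fold_changes(self.occ_t1, self.occ_t2, grid=grid, tol=tol, L=self.L)


class FoldChangeResults:
    """Fitted fold changes plus the grid distribution and derived kinetics."""

    def __init__(self, fold_changes: FoldChanges, base_params: RateParams,
                 distribution: pd.DataFrame, occ_t1: Occupancy, occ_t2: Occupancy,
                 tol: float):
        self.fold_changes = fold_changes
        self.base_params = base_params
        self.distribution = distribution
        self.occ_t1 = occ_t1
        self.occ_t2 = occ_t2
        self.tol = tol

    # -- point estimates -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series({"f_init": self.fold_changes.f_init,
                          "f_rel": self.fold_changes.f_rel})

    @property
    def bse(self) -> pd.Series:
        """Spread (std) of the fold changes across the consistent grid sets."""
        return pd.Series({"f_init": float(self.distribution["f_init"].std(ddof=0)),
                          "f_rel": float(self.distribution["f_rel"].std(ddof=0))})

    @property
    def post_params(self) -> RateParams:
        return self.base_params.scaled(self.fold_changes.f_init, self.fold_changes.f_rel)

    @property
    def residency_before_s(self) -> float:
        return residency_seconds(self.base_params)

    @property
    def residency_after_s(self) -> float:
        return residency_seconds(self.post_params)

    @property
    def init_rate_before(self) -> float:
        """Absolute initiation rate before the change, polymerases/min."""
        return self.base_params.k_init

    @property
    def init_rate_after(self) -> float:
        return self.post_params.k_init

    def simulate_profiles(self, pause_summit: int = 40, n_bp: int = 2000,
                          smooth_sigma_bp: float = 6.0) -> pd.DataFrame:
        """Simulated composite Pol II profiles before and after the change."""
        before = simulate_profile(self.base_params, pause_summit, n_bp=n_bp,
                                  smooth_sigma_bp=smooth_sigma_bp)
        after = simulate_profile(self.post_params, pause_summit, n_bp=n_bp,
                                 smooth_sigma_bp=smooth_sigma_bp)
        return pd.DataFrame({"position": np.arange(n_bp), "before": before,
                             "after": after})

    def plot_profiles(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        prof = self.simulate_profiles(**kwargs)
        ax.plot(prof["position"], prof["before"], label="t1")
        ax.plot(prof["position"], prof["after"], label="t2")
        ax.set_xlabel("distance from TSS (bp)")
        ax.set_ylabel("simulated Pol II density (pol/bp)")
        ax.legend()
        return ax

    def summary(self) -> str:
        dist = self.distribution
        lines = [
            "Two-compartment Pol II fold-change fit",
            "=" * 54,
            f"consistent base sets : {len(dist)} (tol {self.tol:g})",
            f"occ t1 (P, b)        : {self.occ_t1.P:.4g}, {self.occ_t1.b:.4g}",
            f"occ t2 (P, b)        : {self.occ_t2.P:.4g}, {self.occ_t2.b:.4g}",
            "-" * 54,
            f"f_init : {self.fold_changes.f_init:8.4f}   "
            f"[{dist['f_init'].min():.4f}, {dist['f_init'].max():.4f}] across grid",
            f"f_rel  : {self.fold_changes.f_rel:8.4f}   "
            f"[{dist['f_rel'].min():.4f}, {dist['f_rel'].max():.4f}] across grid",
            "-" * 54,
            f"base set: k_init={self.base_params.k_init:.4g}/min, "
            f"k_pre={self.base_params.k_pre:.4g}/min, "
            f"k_rel={self.base_params.k_rel:.4g}/min, "
            f"k_elong={self.base_params.k_elong:.4g} bp/min",
            f"pause residency : {self.residency_before_s:.1f} s -> "
            f"{self.residency_after_s:.1f} s",
            f"initiation rate : {self.init_rate_before:.3g} -> "
            f"{self.init_rate_after:.3g} pol/min",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<FoldChangeResults f_init={self.fold_changes.f_init:.4f} "
                f"f_rel={self.fold_changes.f_rel:.4f} n_grid={len(self.distribution)}>")
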