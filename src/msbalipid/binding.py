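"""Sequential lipid-binding equilibrium model for a homodimeric transporter.

Native mass spectrometry resolves the discrete lipid-bound states of a
protein complex P, PL, PL2, ... PLn.  Stepwise (macroscopic) equilibria

    PL(n-1) + L  <=>  PLn,    K_An = [PLn] / ([PL(n-1)] [L])

give the Adair partition function, from which the mole fraction of the
species carrying ``n`` lipids at free lipid concentration ``[L]_free`` is

    F_PLn = [L]_free^n * prod_{j<=n} K_Aj  /  (1 + sum_i [L]_free^i * prod_{j<=i} K_Aj)

Because the protein is at micromolar concentration, bound lipid depletes the
free pool; ``[L]_free`` is obtained by solving the mass-balance equation

    [L]_free = [L]_total - [P]_total * sum_i i * F_PLi([L]_free)

self-consistently.  The model is fit to observed mole fractions by
minimising an unweighted sum of squared residuals ("pseudo-chi^2") over all
titration points and all species, including the apo state.

Units: concentrations in uM, association constants in 1/uM, dissociation
constants K_Dn = 1/K_An in uM.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize

__all__ = [
    "BindingModel",
    "TitrationPoint",
    "TitrationSeries",
    "FitResult",
    "ReplicateSummary",
    "FitOptions",
    "mole_fractions",
    "mean_bound",
    "solve_free_lipid",
    "predict_abundances",
    "pseudo_chi2",
    "fit_series",
    "fit_pooled",
    "infer_n_max",
    "aggregate_replicates",
    "cooperativity_profile",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingModel:
    """Macroscopic association constants K_A1..K_An (1/uM) of the sequential model."""

    ka: tuple[float, ...]

    def __post_init__(self) -> None:
        ka = tuple(float(k) for k in self.ka)
        if len(ka) < 1:
            raise ValueError("BindingModel needs at least one binding event")
        if not all(math.isfinite(k) and k > 0 for k in ka):
            raise ValueError(f"association constants must be positive and finite, got {ka}")
        object.__setattr__(self, "ka", ka)

    @property
    def n_max(self) -> int:
        return len(self.ka)

    @property
    def kd(self) -> tuple[float, ...]:
        """Stepwise dissociation constants K_Dn = 1/K_An (uM)."""
        return tuple(1.0 / k for k in self.ka)

    @classmethod
    def from_kd(cls, kd: Sequence[float]) -> "BindingModel":
        return cls(tuple(1.0 / float(k) for k in kd))

    def _cumlog_ka(self) -> np.ndarray:
        # cumulative log beta_n = sum_{j<=n} log K_Aj, with beta_0 = 1
        return np.concatenate(([0.0], np.cumsum(np.log(self.ka))))


@dataclass(frozen=True)
class TitrationPoint:
    """One titration condition: total lipid, total protein (dimer), observed mole fractions."""

    l_total: float
    p_total: float
    f_obs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.l_total < 0:
            raise ValueError(f"l_total must be >= 0, got {self.l_total}")
        if self.p_total <= 0:
            raise ValueError(f"p_total must be > 0, got {self.p_total}")
        f = np.asarray(self.f_obs, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("f_obs must be a non-empty 1-d sequence")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-9):
            raise ValueError(f"mole fractions must lie in [0, 1], got {f}")
        total = f.sum()
        if total <= 0:
            raise ValueError("observed mole fractions sum to zero")
        f = np.clip(f, 0.0, None) / np.clip(f, 0.0, None).sum()
        object.__setattr__(self, "f_obs", tuple(f))


@dataclass(frozen=True)
class TitrationSeries:
    """One replicate titration: ordered points plus identifying labels."""

    points: tuple[TitrationPoint, ...]
    replicate_id: str = "rep1"
    lipid_name: str = "lipid"
    condition: str = ""

    def __post_init__(self) -> None:
        points = tuple(self.points)
        if len(points) < 3:
            raise ValueError("a titration series needs at least 3 points")
        l_totals = [p.l_total for p in points]
        if len(set(l_totals)) < 3:
            raise ValueError("titration points must span >= 3 distinct l_total values")
        p_totals = {p.p_total for p in points}
        if max(p_totals) - min(p_totals) > 1e-9 * max(p_totals):
            raise ValueError("all points in a series must share p_total")
        object.__setattr__(self, "points", points)

    @property
    def max_observed_n(self) -> int:
        return max(len(p.f_obs) for p in self.points) - 1


@dataclass(frozen=True)
class FitResult:
    model: BindingModel
    chi2: float
    converged: bool
    n_points: int
    boundary: bool = False
    message: str = ""

    @property
    def kd(self) -> tuple[float, ...]:
        return self.model.kd

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-binding-event mean and standard deviation of K_D across replicates."""

    kd_mean: tuple[float, ...]
    kd_sd: tuple[float, ...] | None
    n_replicates: int
    n_excluded: int = 0


@dataclass(frozen=True)
class FitOptions:
    """Deterministic fit settings.

    log10 K_A is optimised within ``log10_ka_bounds`` (default spans
    K_D from 1e-3 to 1e4 uM).  A coarse enumeration over ``prescan_grid``
    (per dimension) selects ``n_starts`` starting points for the local
    optimiser; no randomness is involved anywhere.
    """

    log10_ka_bounds: tuple[float, float] = (-4.0, 3.0)
    prescan_grid: tuple[float, ...] = (-3.0, -1.5, 0.0, 1.5, 3.0)
    n_starts: int = 3
    gtol: float = 1e-10
    boundary_margin: float = 1e-3


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def mole_fractions(model: BindingModel, l_free: float) -> np.ndarray:
    """Mole fractions (F_PL0 .. F_PLn) at free lipid concentration ``l_free`` (uM).

    Evaluated in the log domain so extreme K_A * l_free products cannot
    overflow; the result always sums to 1 exactly up to floating rounding.
    """
    l_free = float(l_free)
    if l_free < 0:
        raise ValueError(f"l_free must be >= 0, got {l_free}")
    n = model.n_max
    if l_free == 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    log_terms = model._cumlog_ka() + np.arange(n + 1) * math.log(l_free)
    log_terms -= log_terms.max()
    f = np.exp(log_terms)
    f /= f.sum()
    return f


def mean_bound(model: BindingModel, l_free: float) -> float:
    """Average number of bound lipids per protein, sum_i i * F_PLi."""
    f = mole_fractions(model, l_free)
    return float(np.arange(f.size) @ f)


def solve_free_lipid(model: BindingModel, l_total: float, p_total: float,
                     tol: float = 1e-12) -> float:
    """Free lipid concentration (uM) satisfying the depletion mass balance.

    Solves l_free + p_total * nbar(l_free) = l_total by bracketed root
    finding on [0, l_total]; the residual is strictly increasing, so the
    root is unique.
    """
    if l_total < 0:
        raise ValueError(f"l_total must be >= 0, got {l_total}")
    if p_total <= 0:
        raise ValueError(f"p_total must be > 0, got {p_total}")
    if l_total == 0.0:
        return 0.0

    def residual(x: float) -> float:
        return x + p_total * mean_bound(model, x) - l_total

    if residual(l_total) <= 0:  # no depletion possible beyond the total
        return float(l_total)
    root = brentq(residual, 0.0, l_total, xtol=tol, rtol=8.881784197001252e-16,
                  maxiter=200)
    res = residual(root)
    if abs(res) > 1e-10 * max(1.0, l_total):
        raise RuntimeError(
            f"free-lipid solver residual {res:.3e} exceeds tolerance "
            f"(l_total={l_total}, p_total={p_total}, ka={model.ka})"
        )
    return float(root)


def predict_abundances(model: BindingModel, point: TitrationPoint) -> np.ndarray:
    """Predicted mole fractions at a titration point, depletion included."""
    l_free = solve_free_lipid(model, point.l_total, point.p_total)
    return mole_fractions(model, l_free)


# ---------------------------------------------------------------------------
# objective and fitting
# ---------------------------------------------------------------------------

def _padded_obs(point: TitrationPoint, n_max: int) -> np.ndarray:
    f = np.asarray(point.f_obs, dtype=float)
    if f.size > n_max + 1:
        raise ValueError(
            f"observed mole-fraction vector has {f.size} species but the model "
            f"allows only {n_max + 1}"
        )
    if f.size < n_max + 1:
        f = np.concatenate([f, np.zeros(n_max + 1 - f.size)])
    return f


def pseudo_chi2(model: BindingModel, series: TitrationSeries) -> float:
    """Unweighted sum of squared mole-fraction residuals over points and species.

    The apo species is included in the sum; since fractions sum to one this
    is a uniform reweighting of the bound-species-only objective and does
    not move the minimiser.
    """
    total = 0.0
    for point in series.points:
        f_obs = _padded_obs(point, model.n_max)
        f_calc = predict_abundances(model, point)
        d = f_obs - f_calc
        total += float(d @ d)
    return total


def _chi2_multi(model: BindingModel, series_list: Sequence[TitrationSeries]) -> float:
    return sum(pseudo_chi2(model, s) for s in series_list)


def infer_n_max(series: TitrationSeries, threshold: float = 0.01) -> int:
    """Largest bound-lipid count whose mole fraction exceeds ``threshold`` anywhere."""
    n = 0
    for point in series.points:
        for i, f in enumerate(point.f_obs):
            if i > 0 and f > threshold:
                n = max(n, i)
    return n


def _fit(series_list: Sequence[TitrationSeries], n_max: int,
         options: FitOptions) -> FitResult:
    n_points = sum(len(s.points) for s in series_list)
    lo, hi = options.log10_ka_bounds

    # unidentifiable: no bound species observed anywhere
    saturation = max(sum(p.f_obs[1:]) for s in series_list for p in s.points)
    if saturation < 1e-6:
        model = BindingModel(tuple(10.0 ** lo for _ in range(n_max)))
        return FitResult(model=model, chi2=_chi2_multi(model, series_list),
                         converged=False, n_points=n_points, boundary=True,
                         message="no bound species observed; K_D at upper bound")

    def objective(x: np.ndarray) -> float:
        return _chi2_multi(BindingModel(tuple(10.0 ** xi for xi in x)), series_list)

    # deterministic coarse enumeration picks local-optimiser starting points
    grid = [g for g in options.prescan_grid if lo <= g <= hi]
    candidates = sorted(
        itertools.product(grid, repeat=n_max),
        key=lambda x: (objective(np.asarray(x)), -x[0]),
    )
    starts = candidates[: options.n_starts]

    best_x, best_chi2 = None, math.inf
    bounds = [(lo, hi)] * n_max
    for x0 in starts:
        res = minimize(objective, np.asarray(x0, dtype=float), method="L-BFGS-B",
                       bounds=bounds, options={"ftol": 1e-14, "gtol": options.gtol,
                                               "maxiter": 500})
        better = res.fun < best_chi2 * (1 - 1e-12)
        tie = abs(res.fun - best_chi2) <= 1e-12 * max(best_chi2, 1e-30)
        # ties broken by the smallest K_D1, i.e. the largest K_A1
        if better or (tie and best_x is not None and res.x[0] > best_x[0]):
            best_x, best_chi2 = res.x.copy(), float(res.fun)

    model = BindingModel(tuple(10.0 ** xi for xi in best_x))
    boundary = bool(np.any(best_x < lo + options.boundary_margin)
                    or np.any(best_x > hi - options.boundary_margin))
    msg = "parameter at bound" if boundary else ""
    return FitResult(model=model, chi2=best_chi2, converged=True,
                     n_points=n_points, boundary=boundary, message=msg)


def fit_series(series: TitrationSeries, n_max: int | None = None,
               options: FitOptions | None = None) -> FitResult:
    """Globally fit the sequential binding model to one replicate titration.

    ``n_max`` defaults to the largest bound-lipid count whose observed mole
    fraction exceeds 1% at any titration point.  The fit is deterministic:
    a fixed log10(K_A) enumeration seeds a bounded local optimiser.
    """
    options = options or FitOptions()
    if n_max is None:
        n_max = infer_n_max(series)
    if n_max < 1:
        raise ValueError("n_max must be >= 1 (no bound species detected?)")
    if len(series.points) < n_max + 2:
        raise ValueError(
            f"need at least n_max + 2 = {n_max + 2} titration points, "
            f"got {len(series.points)}"
        )
    return _fit([series], n_max, options)


def fit_pooled(series_list: Sequence[TitrationSeries], n_max: int | None = None,
               options: FitOptions | None = None) -> FitResult:
    """Pool replicates into a single fit (non-default alternative to
    fitting each replicate independently and averaging the K_Ds)."""
    options = options or FitOptions()
    if not series_list:
        raise ValueError("no series supplied")
    if n_max is None:
        n_max = max(infer_n_max(s) for s in series_list)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    return _fit(list(series_list), n_max, options)


def aggregate_replicates(fits: Sequence[FitResult]) -> ReplicateSummary:
    """Mean and sample standard deviation of K_D per binding event across replicates.

    Boundary-flagged or non-converged fits are excluded with a warning; with
    fewer than two usable replicates the standard deviation is not reported.
    """
    usable = [f for f in fits if f.converged and not f.boundary]
    excluded = len(fits) - len(usable)
    if excluded:
        warnings.warn(
            f"excluded {excluded} boundary-flagged or non-converged fit(s) "
            "from replicate aggregation", stacklevel=2)
    if not usable:
        raise ValueError("no converged, non-boundary fits to aggregate")
    n_max = usable[0].model.n_max
    if any(f.model.n_max != n_max for f in usable):
        raise ValueError("all fits must share the same number of binding events")
    kd = np.array([f.kd for f in usable])
    mean = tuple(kd.mean(axis=0))
    sd = tuple(kd.std(axis=0, ddof=1)) if len(usable) >= 2 else None
    return ReplicateSummary(kd_mean=mean, kd_sd=sd, n_replicates=len(usable),
                            n_excluded=excluded)


# ---------------------------------------------------------------------------
# cooperativity
# ---------------------------------------------------------------------------

def _statistical_factor(n: int, n_sites: int) -> float:
    # macroscopic/intrinsic K_D ratio for N identical independent sites
    return n / (n_sites - n + 1)


def cooperativity_profile(summary: ReplicateSummary | Sequence[float],
                          n_sites: int | None = None) -> dict:
    """Step-to-step K_D ratios, raw and corrected for the statistical factor.

    For N identical, independent sites the macroscopic constants follow
    K_Dn = K_intrinsic * n / (N - n + 1); dividing each macroscopic K_Dn by
    this factor before forming the ratio r_n = K_D(n+1)/K_Dn removes purely
    combinatorial trends, so corrected r_n < 1 indicates genuine positive
    cooperativity.  The corrected statistic is an extension beyond a bare
    qualitative reading of the K_D sequence and is labelled as such.
    """
    kd = np.asarray(summary.kd_mean if isinstance(summary, ReplicateSummary)
                    else summary, dtype=float)
    n_max = kd.size
    if n_max < 2:
        raise ValueError("cooperativity ratios need at least two binding events")
    if n_sites is None:
        n_sites = n_max
    if n_sites < n_max:
        raise ValueError("n_sites must be >= the number of binding events")
    factors = np.array([_statistical_factor(n, n_sites) for n in range(1, n_max + 1)])
    kd_intrinsic = kd / factors
    raw = kd[1:] / kd[:-1]
    corrected = kd_intrinsic[1:] / kd_intrinsic[:-1]
    labels = tuple(
        "positive cooperativity" if r < 1
        else ("negative cooperativity" if r > 1 else "non-cooperative")
        for r in corrected
    )
    return {
        "raw_ratio": tuple(raw),
        "corrected_ratio": tuple(corrected),
        "statistical_factor": tuple(factors),
        "label": labels,
        "note": "corrected ratio divides each macroscopic K_D by n/(N-n+1); "
                "a derived statistic, not a direct experimental readout",
    }
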