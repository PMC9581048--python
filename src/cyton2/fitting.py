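"""Least-squares fitting of the reduced Cyton2 model to FACS count data.

The reduced model has seven free parameters per condition: two for each of
the first-division, destiny and death timer distributions (lognormal
median/shape or normal mean/SD) plus the constant subsequent division time
``m``. The founder count ``n0`` is not fitted; it is fixed from the cell
numbers at the earliest harvest time.

The cost is the unweighted residual sum of squares over every
(time, generation, replicate) record,

    C(theta) = sum_i sum_g sum_r (n_{g,r}(t_i) - y_g(t_i; theta))^2.

Point estimates come from bounded trust-region least squares
(Levenberg-Marquardt class) restarted from many random initial vectors;
positive parameters are optimized in log space. Uncertainty comes from a
replicate bootstrap: within each time point, replicate generation-profiles
are resampled with replacement as units, the model refit, and percentile
intervals read off the refits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .distributions import make_distribution
from .mean_model import CytonParameters, _gen_counts

__all__ = [
    "GenerationCountTable",
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "rss",
    "fit",
    "bootstrap_ci",
    "joint_fit",
    "predict_combined",
    "count_free_parameters",
    "enumerate_timepoint_removals",
    "ablation_study",
    "AblationResult",
    "NegativeVarianceError",
]


# ---------------------------------------------------------------------------
# data container

class GenerationCountTable:
    """Live-cell counts per generation, replicate and harvest time.

    Wraps a tidy DataFrame with columns ``time_h``, ``replicate``,
    ``generation``, ``count``. ``n0`` is the mean over replicates of the
    total cell number at the earliest time point (the model's fixed
    founder count).
    """

    REQUIRED = ("time_h", "replicate", "generation", "count")

    def __init__(self, frame: pd.DataFrame, condition: str = ""):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        if (frame["count"] < 0).any():
            raise ValueError("negative counts present")
        if (frame["generation"] < 0).any():
            raise ValueError("negative generations present")
        dup = frame.duplicated(["time_h", "replicate", "generation"])
        if dup.any():
            keys = frame.loc[dup, ["time_h", "replicate", "generation"]]
            raise ValueError(
                f"duplicate (time, replicate, generation) rows:\n{keys}")
        self.frame = frame.sort_values(
            ["time_h", "replicate", "generation"]).reset_index(drop=True)
        self.condition = condition

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frame["time_h"].to_numpy())

    @property
    def max_generation(self) -> int:
        return int(self.frame["generation"].max())

    @property
    def n_replicates(self) -> int:
        return self.frame["replicate"].nunique()

    @property
    def n0(self) -> float:
        t0 = self.times[0]
        first = self.frame[self.frame["time_h"] == t0]
        return float(first.groupby("replicate")["count"].sum().mean())

    def __len__(self) -> int:
        return len(self.frame)

    def resample_replicates(self, rng: np.random.Generator,
                            n_replicates: Optional[int] = None
                            ) -> "GenerationCountTable":
        """Bootstrap: per time point, draw replicates with replacement.

        A replicate's full generation profile at a time point moves as one
        unit, preserving the within-sample generation structure.
        """
        pieces = []
        for t, grp in self.frame.groupby("time_h", sort=True):
            reps = np.unique(grp["replicate"].to_numpy())
            k = n_replicates if n_replicates is not None else len(reps)
            chosen = rng.choice(reps, size=k, replace=True)
            for new_r, old_r in enumerate(chosen):
                block = grp[grp["replicate"] == old_r].copy()
                block["replicate"] = new_r
                pieces.append(block)
        return GenerationCountTable(pd.concat(pieces, ignore_index=True),
                                    condition=self.condition)

    def drop_times(self, removed: Sequence[int]) -> "GenerationCountTable":
        """Remove harvest time points by index into the sorted time grid."""
        keep = np.delete(self.times, list(removed))
        sub = self.frame[self.frame["time_h"].isin(keep)]
        return GenerationCountTable(sub.copy(), condition=self.condition)


# ---------------------------------------------------------------------------
# parameter vector <-> model

_LOGNORMAL_NAMES = ("m_div0", "s_div0", "m_dd", "s_dd", "m_die", "s_die", "m")
_NORMAL_NAMES = ("mu_div0", "sigma_div0", "mu_dd", "sigma_dd",
                 "mu_die", "sigma_die", "m")

#: start ranges; also the optimization bounds (log-space optimization)
_DEFAULT_BOUNDS = {
    "lognormal": {
        "location": (0.1, 200.0),   # medians, hours
        "shape": (0.05, 1.5),       # lognormal shape
        "m": (5.0, 50.0),           # subsequent division time, hours
    },
    "normal": {
        "location": (0.1, 200.0),   # means, hours
        "shape": (0.5, 40.0),       # SDs, hours
        "m": (5.0, 50.0),
    },
}


@dataclass
class FitConfig:
    """Fitting options: timer family, multi-start count, bounds, seed."""

    family: str = "lognormal"          # 'lognormal' or 'normal'
    n_starts: int = 100
    seed: int = 0
    bounds: Optional[dict] = None      # overrides _DEFAULT_BOUNDS entries
    quad_nodes: int = 64               # destiny-integral nodes during fits
    max_nfev: Optional[int] = None

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise ValueError("family must be 'lognormal' or 'normal'")

    @property
    def param_names(self) -> tuple[str, ...]:
        return (_LOGNORMAL_NAMES if self.family == "lognormal"
                else _NORMAL_NAMES)

    def bounds_array(self) -> np.ndarray:
        base = dict(_DEFAULT_BOUNDS[self.family])
        if self.bounds:
            base.update(self.bounds)
        loc, shape, m = base["location"], base["shape"], base["m"]
        per = [loc, shape, loc, shape, loc, shape, m]
        return np.array(per, dtype=float)   # (7, 2)


def theta_to_params(theta: Sequence[float], family: str,
                    n0: float) -> CytonParameters:
    """Build model parameters from a 7-vector in canonical order."""
    t = np.asarray(theta, dtype=float)
    if family == "lognormal":
        mk = lambda m_, s_: make_distribution("lognormal", m=m_, s=s_)
    else:
        mk = lambda m_, s_: make_distribution("normal", mu=m_, sigma=s_)
    return CytonParameters(
        dist_div0=mk(t[0], t[1]), subsequent=float(t[6]),
        dist_dd=mk(t[2], t[3]), dist_die=mk(t[4], t[5]), n0=n0)


def params_to_theta(params: CytonParameters) -> np.ndarray:
    fam = params.dist_div0.family
    keys = ("m", "s") if fam == "lognormal" else ("mu", "sigma")
    return np.array([
        params.dist_div0.params[keys[0]], params.dist_div0.params[keys[1]],
        params.dist_dd.params[keys[0]], params.dist_dd.params[keys[1]],
        params.dist_die.params[keys[0]], params.dist_die.params[keys[1]],
        float(params.subsequent)])


# ---------------------------------------------------------------------------
# cost

class _Problem:
    """Precomputed index structure for fast residual evaluation."""

    def __init__(self, data: GenerationCountTable, family: str,
                 quad_nodes: int, n0: Optional[float] = None):
        self.family = family
        self.quad_nodes = quad_nodes
        self.times = data.times
        self.G = data.max_generation
        self.n0 = data.n0 if n0 is None else n0
        f = data.frame
        t_index = {t: i for i, t in enumerate(self.times)}
        self.t_idx = f["time_h"].map(t_index).to_numpy()
        self.g_idx = f["generation"].to_numpy()
        self.counts = f["count"].to_numpy(dtype=float)

    def predicted(self, theta: np.ndarray) -> np.ndarray:
        params = theta_to_params(theta, self.family, self.n0)
        Y = _gen_counts(params, self.times, self.G,
                        quad_nodes=self.quad_nodes)
        return Y[self.g_idx, self.t_idx]

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.counts - self.predicted(theta)

    def rss(self, theta: np.ndarray) -> float:
        res = self.residuals(theta)
        return float(res @ res)


def rss(params: CytonParameters, data: GenerationCountTable,
        quad_nodes: Optional[int] = 256) -> float:
    """Residual sum of squares of the model against a count table.

    Works for any timer families (including point masses); the model is
    evaluated at the table's times with the parameters' own ``n0``.
    """
    times = data.times
    Y = _gen_counts(params, times, data.max_generation,
                    quad_nodes=quad_nodes)
    t_index = {t: i for i, t in enumerate(times)}
    f = data.frame
    pred = Y[f["generation"].to_numpy(),
             f["time_h"].map(t_index).to_numpy()]
    res = f["count"].to_numpy(dtype=float) - pred
    return float(res @ res)


# ---------------------------------------------------------------------------
# fit results

@dataclass
class FitResult:
    """Best-of-multi-start least-squares estimate for one condition."""

    family: str
    param_names: tuple[str, ...]
    theta: np.ndarray                   # best point estimate (7,)
    rss: float
    n0: float
    start_rss: np.ndarray               # converged RSS per start
    start_thetas: np.ndarray = field(repr=False)
    config: FitConfig = field(repr=False, default=None)
    condition: str = ""

    @property
    def params(self) -> dict:
        return dict(zip(self.param_names, self.theta))

    def to_cyton_parameters(self) -> CytonParameters:
        return theta_to_params(self.theta, self.family, self.n0)

    @property
    def n_free_parameters(self) -> int:
        return len(self.theta)


@dataclass
class BootstrapResult:
    """Percentile bootstrap uncertainty around a fit."""

    thetas: np.ndarray                  # (B_ok, 7) refit estimates
    ci: dict                            # name -> (lo, hi)
    band_times: np.ndarray
    total_band: np.ndarray              # (2, len(band_times)) lo/hi totals
    gen_bands: np.ndarray               # (2, G+1, len(band_times))
    n_failed: int


def _single_fit(prob: _Problem, x0_log: np.ndarray, lb: np.ndarray,
                ub: np.ndarray, max_nfev) -> tuple[np.ndarray, float]:
    def f(xlog):
        return prob.residuals(np.exp(xlog))

    try:
        sol = least_squares(f, x0_log, bounds=(lb, ub), method="trf",
                            max_nfev=max_nfev)
        return np.exp(sol.x), float(2 * sol.cost)
    except Exception:
        return np.exp(x0_log), np.inf


def fit(data: GenerationCountTable,
        config: Optional[FitConfig] = None) -> FitResult:
    """Multi-start bounded least squares for one condition.

    Initial vectors are drawn uniformly at random within the configured
    bounds; every start's converged RSS is recorded and the lowest kept.
    """
    config = config or FitConfig()
    if len(data.times) < 3:
        raise ValueError("need at least 3 time points to fit")
    prob = _Problem(data, config.family, config.quad_nodes)
    bounds = config.bounds_array()
    lb, ub = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    rng = np.random.default_rng(config.seed)
    starts = np.exp(rng.uniform(lb, ub, size=(config.n_starts, 7)))
    thetas, rsses = [], []
    for x0 in starts:
        th, r2 = _single_fit(prob, np.log(x0), lb, ub, config.max_nfev)
        thetas.append(th)
        rsses.append(r2)
    rsses = np.asarray(rsses)
    if not np.isfinite(rsses).any():
        raise RuntimeError("all starts failed to converge")
    best = int(np.argmin(rsses))
    return FitResult(family=config.family, param_names=config.param_names,
                     theta=thetas[best], rss=float(rsses[best]),
                     n0=prob.n0, start_rss=rsses,
                     start_thetas=np.asarray(thetas), config=config,
                     condition=data.condition)


def bootstrap_ci(data: GenerationCountTable, best_fit: FitResult,
                 B: int = 1000, seed: int = 0,
                 band_times: Optional[np.ndarray] = None,
                 n_band_points: int = 121) -> BootstrapResult:
    """Replicate bootstrap: resample, refit from the best estimate, and
    report 95% percentile intervals and extrapolation bands."""
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    config = best_fit.config or FitConfig(family=best_fit.family)
    rng = np.random.default_rng(seed)
    bounds = config.bounds_array()
    lb, ub = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    x0 = np.log(np.clip(best_fit.theta, np.exp(lb), np.exp(ub)))
    thetas, failed = [], 0
    for _ in range(B):
        boot = data.resample_replicates(rng)
        prob = _Problem(boot, config.family, config.quad_nodes)
        th, r2 = _single_fit(prob, x0, lb, ub, config.max_nfev)
        if np.isfinite(r2):
            thetas.append(th)
        else:
            failed += 1
    thetas = np.asarray(thetas)
    ci = {name: tuple(np.percentile(thetas[:, i], [2.5, 97.5]))
          for i, name in enumerate(best_fit.param_names)}
    if band_times is None:
        band_times = np.linspace(data.times[0], data.times[-1],
                                 n_band_points)
    band_times = np.asarray(band_times, dtype=float)
    G = data.max_generation
    curves = np.empty((len(thetas), G + 1, len(band_times)))
    for i, th in enumerate(thetas):
        params = theta_to_params(th, config.family, best_fit.n0)
        curves[i] = _gen_counts(params, band_times, G,
                                quad_nodes=config.quad_nodes)
    gen_bands = np.percentile(curves, [2.5, 97.5], axis=0)
    total_band = np.percentile(curves.sum(axis=1), [2.5, 97.5], axis=0)
    return BootstrapResult(thetas=thetas, ci=ci, band_times=band_times,
                           total_band=total_band, gen_bands=gen_bands,
                           n_failed=failed)


# ---------------------------------------------------------------------------
# joint fitting with shared parameters

@dataclass
class JointFitResult:
    """Simultaneous fit of several conditions with shared parameters."""

    fits: dict                          # condition -> FitResult
    shared: tuple[str, ...]
    shared_values: dict
    rss: float
    start_rss: np.ndarray

    @property
    def n_free_parameters(self) -> int:
        n = len(self.fits)
        return 7 * n - (n - 1) * len(self.shared)


def joint_fit(datasets: dict, shared: Sequence[str] = ("m",),
              config: Optional[FitConfig] = None) -> JointFitResult:
    """Fit several count tables at once with some parameters shared.

    The cost is the sum of each condition's RSS; shared parameters (by
    canonical name, e.g. ``"m"``) are constrained equal across conditions.
    The default multi-start count doubles to 200 because of the larger
    search space.
    """
    config = config or FitConfig(n_starts=200)
    names = config.param_names
    shared = tuple(shared)
    for s in shared:
        if s not in names:
            raise ValueError(f"shared name {s!r} is not a model parameter "
                             f"(choose from {names})")
    conditions = list(datasets)
    if len(conditions) < 1:
        raise ValueError("need at least one dataset")
    if len(conditions) == 1:
        single = fit(datasets[conditions[0]], replace(config, n_starts=max(
            config.n_starts // 2, 1)))
        return JointFitResult(
            fits={conditions[0]: single}, shared=shared,
            shared_values={s: single.params[s] for s in shared},
            rss=single.rss, start_rss=single.start_rss)

    probs = {c: _Problem(datasets[c], config.family, config.quad_nodes)
             for c in conditions}
    shared_idx = [names.index(s) for s in shared]
    free_idx = [i for i in range(7) if i not in shared_idx]
    n_cond = len(conditions)
    dim = len(shared_idx) + n_cond * len(free_idx)

    def unpack(x: np.ndarray) -> dict:
        thetas = {}
        sh = x[:len(shared_idx)]
        for j, c in enumerate(conditions):
            th = np.empty(7)
            th[shared_idx] = sh
            th[free_idx] = x[len(shared_idx) + j * len(free_idx):
                             len(shared_idx) + (j + 1) * len(free_idx)]
            thetas[c] = th
        return thetas

    def residuals(xlog):
        thetas = unpack(np.exp(xlog))
        return np.concatenate(
            [probs[c].residuals(thetas[c]) for c in conditions])

    bounds = config.bounds_array()
    lb7, ub7 = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    lb = np.concatenate([lb7[shared_idx],
                         np.tile(lb7[free_idx], n_cond)])
    ub = np.concatenate([ub7[shared_idx],
                         np.tile(ub7[free_idx], n_cond)])
    # each condition's residuals depend only on the shared block and its
    # own free block; the sparsity pattern cuts finite-difference cost
    sizes = [len(probs[c].counts) for c in conditions]
    sparsity = np.zeros((sum(sizes), dim), dtype=bool)
    row = 0
    for j, sz in enumerate(sizes):
        sparsity[row:row + sz, :len(shared_idx)] = True
        start = len(shared_idx) + j * len(free_idx)
        sparsity[row:row + sz, start:start + len(free_idx)] = True
        row += sz
    rng = np.random.default_rng(config.seed)

    def pack(thetas: dict) -> np.ndarray:
        x = np.empty(dim)
        x[:len(shared_idx)] = np.mean(
            [thetas[c][shared_idx] for c in conditions], axis=0)
        for j, c in enumerate(conditions):
            x[len(shared_idx) + j * len(free_idx):
              len(shared_idx) + (j + 1) * len(free_idx)] = \
                thetas[c][free_idx]
        return x

    # warm start from cheap independent per-condition fits; the random
    # starts below still explore the full box
    indep = {c: fit(datasets[c], replace(
        config, n_starts=max(10, config.n_starts // 10),
        seed=int(rng.integers(2**31)))) for c in conditions}
    warm = np.clip(pack({c: np.log(indep[c].theta) for c in conditions}),
                   lb, ub)
    starts = [warm] + [rng.uniform(lb, ub, size=dim)
                       for _ in range(max(config.n_starts - 1, 0))]
    xs, rsses = [], []
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub),
                                method="trf", jac_sparsity=sparsity,
                                max_nfev=config.max_nfev)
            xs.append(sol.x)
            rsses.append(float(2 * sol.cost))
        except Exception:
            xs.append(x0)
            rsses.append(np.inf)
    rsses = np.asarray(rsses)
    if not np.isfinite(rsses).any():
        raise RuntimeError("all joint-fit starts failed to converge")
    best = int(np.argmin(rsses))
    thetas = unpack(np.exp(xs[best]))
    fits = {}
    for c in conditions:
        prob = probs[c]
        fits[c] = FitResult(
            family=config.family, param_names=names, theta=thetas[c],
            rss=prob.rss(thetas[c]), n0=prob.n0, start_rss=rsses,
            start_thetas=np.asarray([unpack(np.exp(x))[c] for x in xs]),
            config=config, condition=str(c))
    shared_values = {s: float(thetas[conditions[0]][names.index(s)])
                     for s in shared}
    return JointFitResult(fits=fits, shared=shared,
                          shared_values=shared_values,
                          rss=float(rsses[best]), start_rss=rsses)


# ---------------------------------------------------------------------------
# combined-stimulus prediction (additive Gaussian timers)

class NegativeVarianceError(ValueError):
    """Additive variance prediction went non-positive."""


def predict_combined(base: FitResult, *delta_fits: FitResult,
                     m: Optional[float] = None, n0: Optional[float] = None,
                     variance_floor: Optional[float] = None
                     ) -> CytonParameters:
    """Predict a combined-stimulus condition from Gaussian timer fits.

    For each timer (first division, destiny, death) the combined mean is
    ``mu_base + sum_x (mu_x - mu_base)`` and the combined variance
    ``sigma_base^2 + sum_x (sigma_x^2 - sigma_base^2)``. All fits must use
    normal timers. A non-positive combined variance raises
    :class:`NegativeVarianceError` unless ``variance_floor`` is given.
    """
    fits = (base,) + delta_fits
    if any(f.family != "normal" for f in fits):
        raise ValueError("combined prediction requires normal-timer fits")
    names = base.param_names
    mus, sigmas = {}, {}
    for timer, (mu_key, sd_key) in {
            "div0": ("mu_div0", "sigma_div0"),
            "dd": ("mu_dd", "sigma_dd"),
            "die": ("mu_die", "sigma_die")}.items():
        mu_b = base.params[mu_key]
        var_b = base.params[sd_key] ** 2
        mu = mu_b + sum(f.params[mu_key] - mu_b for f in delta_fits)
        var = var_b + sum(f.params[sd_key] ** 2 - var_b
                          for f in delta_fits)
        if var <= 0:
            if variance_floor is None:
                raise NegativeVarianceError(
                    f"combined variance for {timer} is {var:.4g} <= 0")
            var = variance_floor
        mus[timer], sigmas[timer] = mu, np.sqrt(var)
    m_val = float(m if m is not None else base.params["m"])
    return CytonParameters(
        dist_div0=make_distribution("normal", mu=mus["div0"],
                                    sigma=sigmas["div0"]),
        subsequent=m_val,
        dist_dd=make_distribution("normal", mu=mus["dd"],
                                  sigma=sigmas["dd"]),
        dist_die=make_distribution("normal", mu=mus["die"],
                                   sigma=sigmas["die"]),
        n0=float(n0 if n0 is not None else base.n0))


# ---------------------------------------------------------------------------
# bookkeeping and the data-requirement study

def count_free_parameters(n_conditions: int = 1,
                          shared: Sequence[str] = (),
                          model: str = "reduced",
                          generations: Optional[int] = None) -> int:
    """Free-parameter count for a fitting configuration.

    Reduced model: 7 per condition, with each shared parameter counted
    once across conditions (3 conditions sharing ``m`` -> 19). Full model:
    6 + 2g for ``g`` modelled generations.
    """
    if model == "full":
        if generations is None:
            raise ValueError("full model needs the generation count")
        return 6 + 2 * generations
    if model != "reduced":
        raise ValueError("model must be 'reduced' or 'full'")
    return 7 * n_conditions - (n_conditions - 1) * len(set(shared))


def enumerate_timepoint_removals(n_timepoints: int, min_retained: int = 3,
                                 anchor: tuple[int, int] = (0, 1)
                                 ) -> list[tuple[int, ...]]:
    """All admissible time-point removal sets for the data-ablation study.

    Rules: at least ``min_retained`` time points stay, at least one point
    is removed, and at least one of the two ``anchor`` indices (the first
    and second harvest, which supply the initial cell number) survives.
    """
    if n_timepoints < min_retained:
        raise ValueError("fewer time points than the retention minimum")
    cases = []
    for k in range(1, n_timepoints - min_retained + 1):
        for combo in itertools.combinations(range(n_timepoints), k):
            if anchor[0] in combo and anchor[1] in combo:
                continue
            cases.append(combo)
    return cases


@dataclass
class AblationResult:
    """RMSE distribution for one time-point-removal case."""

    case: tuple[int, ...]
    rmse: np.ndarray
    n_failed: int

    def summary(self) -> dict:
        return {"case": self.case, "n_removed": len(self.case),
                "median_rmse": float(np.median(self.rmse)),
                "iqr": tuple(np.percentile(self.rmse, [25, 75])),
                "n_failed": self.n_failed}


def ablation_study(data: GenerationCountTable, case: Sequence[int],
                   n_synthetic: int = 1000, replicates: int = 3,
                   seed: int = 0,
                   config: Optional[FitConfig] = None) -> AblationResult:
    """RMSE of fits to subsampled data against the full original dataset.

    For each synthetic dataset: drop the case's time points, draw
    ``replicates`` replicates with replacement per remaining time point,
    fit, then score the fitted model against *all* records of the original
    unaltered table by root-mean-square error. Fit failures are counted
    and excluded rather than raised.
    """
    config = config or FitConfig(n_starts=10)
    rng = np.random.default_rng(seed)
    reduced = data.drop_times(case) if len(case) else data
    full_prob = _Problem(data, config.family, config.quad_nodes)
    rmses, failed = [], 0
    for b in range(n_synthetic):
        boot = reduced.resample_replicates(rng, n_replicates=replicates)
        try:
            res = fit(boot, replace(config,
                                    seed=int(rng.integers(2**31))))
        except (RuntimeError, ValueError):
            failed += 1
            continue
        prob_theta = res.theta
        resid = full_prob.counts - _Problem(
            data, config.family, config.quad_nodes,
            n0=res.n0).predicted(prob_theta)
        rmses.append(float(np.sqrt(np.mean(resid ** 2))))
    return AblationResult(case=tuple(case), rmse=np.asarray(rmses),
                          n_failed=failed)
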