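"""Agent-based realization of Cyton2 family trees and censoring rules.

Each simulation realises one clonal family. The founder draws a time to
first division, a familial destiny time and a familial death time, all
independent. Subsequent division times are drawn once per generation and
shared by every cell of that generation, so division within a family is
perfectly synchronous. A division scheduled at or after ``min(T_dd, T_die)``
does not occur (strict inequality); cells that reach destiny are marked and
stop dividing but remain alive until the familial death time removes the
whole clone.

The module also implements the observation (right-censoring) rules of the
microscopy assay — a timer pre-empted by destiny or death never appears in
data — and a vectorised cohort simulator used as the Monte-Carlo oracle for
the analytic mean model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bayes import bayes_factor_correlation
from .distributions import TimerDistribution
from .mean_model import CytonParameters
from .trees import Cell, FamilyTree

__all__ = [
    "FamilyTimers",
    "ObservableTimers",
    "simulate_family",
    "simulate_generation_counts",
    "apply_censoring",
    "censorship_study",
    "PAIR_NAMES",
]


@dataclass(frozen=True)
class FamilyTimers:
    """The true (uncensored) timers realised for one family."""

    t_div0: float
    m_g: tuple[float, ...]  # per-generation subsequent division times
    t_dd: float
    t_die: float

    def division_times(self) -> np.ndarray:
        """Cumulative calendar times of divisions 1, 2, ... (uncapped)."""
        return self.t_div0 + np.concatenate(
            [[0.0], np.cumsum(self.m_g)]) if self.m_g else np.array(
            [self.t_div0])


@dataclass(frozen=True)
class ObservableTimers:
    """Timers as they would appear in data; ``None`` marks unobserved.

    ``t_ld`` is the last realized division time, the observable proxy for
    the destiny time; under the working assumption T_ld = T_dd it shares
    T_dd's observability (censored exactly when destiny loses to death).
    """

    t_div0: Optional[float]
    m: Optional[float]
    t_ld: Optional[float]
    t_dd: Optional[float]
    t_die: Optional[float]


def _draw_timers(params: CytonParameters, rng: np.random.Generator,
                 max_generation: int) -> FamilyTimers:
    t_div0 = float(params.dist_div0.sample(1, rng)[0])
    t_dd = float(params.dist_dd.sample(1, rng)[0])
    t_die = float(params.dist_die.sample(1, rng)[0])
    if params.is_reduced:
        m_g = (float(params.subsequent),) * max_generation
    else:
        m_g = tuple(float(params.subsequent_dist(g).sample(1, rng)[0])
                    for g in range(1, max_generation + 1))
    return FamilyTimers(t_div0=t_div0, m_g=m_g, t_dd=t_dd, t_die=t_die)


def simulate_family(params: CytonParameters, seed,
                    max_generation: int = 12
                    ) -> tuple[FamilyTree, FamilyTimers]:
    """Simulate one clonal family tree and return it with its true timers.

    The returned tree contains every cell: internal cells have fate
    ``divided`` at their division time, and the final generation has fate
    ``died`` at the familial death time. ``max_generation`` bounds tree
    depth (a family that would divide further raises, rather than silently
    truncating the biology).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    timers = _draw_timers(params, rng, max_generation + 1)
    limit = min(timers.t_dd, timers.t_die)
    # realized division calendar times, strictly before destiny/death
    div_times = []
    t_next = timers.t_div0
    k = 0
    while t_next < limit:
        div_times.append(t_next)
        if k >= max_generation:
            raise RuntimeError(
                f"family exceeded max_generation={max_generation}; "
                "raise the cap or narrow the timer distributions")
        t_next = t_next + timers.m_g[k]
        k += 1
    g_final = len(div_times)
    cells = []
    for g in range(g_final + 1):
        for idx in range(2 ** g):
            label = tuple(
                1 + ((idx >> (g - 1 - j)) & 1) for j in range(g))
            if g < g_final:
                cells.append(Cell(label=label, fate="divided",
                                  fate_time=div_times[g]))
            else:
                cells.append(Cell(label=label, fate="died",
                                  fate_time=timers.t_die))
    tree = FamilyTree.from_cells(params_clone_id(rng), cells)
    return tree, timers


def params_clone_id(rng: np.random.Generator) -> str:
    """Short reproducible clone identifier."""
    return f"sim-{rng.integers(0, 10**9):09d}"


def apply_censoring(true: FamilyTimers) -> ObservableTimers:
    """Apply the observation rules to one family's true timers.

    * the first division is unobserved when it is pre-empted, i.e. when
      ``t_div0 >= min(t_dd, t_die)``;
    * a subsequent division time is observed only when the second division
      also completes before destiny and death;
    * the destiny time is unobserved when death pre-empts it
      (``t_dd > t_die``), and the last-division proxy mirrors it;
    * death is always observed (the retained clones end with a death).
    """
    limit = min(true.t_dd, true.t_die)
    div0_obs = true.t_div0 < limit
    m1 = true.m_g[0] if true.m_g else np.inf
    m_obs = div0_obs and (true.t_div0 + m1 < limit)
    dd_obs = true.t_dd <= true.t_die
    # last realized division time
    t_ld = None
    if div0_obs:
        t = true.t_div0
        t_ld = t
        for m in true.m_g:
            t = t + m
            if t >= limit:
                break
            t_ld = t
    return ObservableTimers(
        t_div0=true.t_div0 if div0_obs else None,
        m=m1 if m_obs else None,
        t_ld=t_ld if dd_obs else None,
        t_dd=true.t_dd if dd_obs else None,
        t_die=true.t_die,
    )


# ---------------------------------------------------------------------------
# vectorised cohort simulation (Monte-Carlo oracle for the mean model)

def simulate_generation_counts(params: CytonParameters, times,
                               n_families: int, seed,
                               max_generation: int = 10
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Mean live-cell counts per generation over many simulated families.

    Returns ``(mean, se)`` arrays of shape ``(max_generation + 1,
    len(times))`` giving the Monte-Carlo estimate of the expected count per
    founder (times ``n0``) and its standard error. This is the simulation
    oracle the analytic expectations are validated against.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    n = int(n_families)
    div0 = params.dist_div0.sample(n, rng)
    dd = params.dist_dd.sample(n, rng)
    die = params.dist_die.sample(n, rng)
    K = max_generation + 1
    if params.is_reduced:
        m = float(params.subsequent)
        steps = np.full((n, K), m)
    else:
        steps = np.column_stack([
            params.subsequent_dist(g).sample(n, rng)
            for g in range(1, K + 1)])
    # calendar times of divisions 1..K per family
    div_cal = div0[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(steps, axis=1)[:, :-1]], axis=1)
    limit = np.minimum(dd, die)
    n_cap = (div_cal < limit[:, None]).sum(axis=1)

    G = max_generation
    mean = np.empty((G + 1, len(times)))
    se = np.empty((G + 1, len(times)))
    for j, t in enumerate(times):
        n_by_t = (div_cal <= t).sum(axis=1)
        g = np.minimum(n_by_t, n_cap)
        alive = die > t
        for gg in range(G + 1):
            p = np.mean(alive & (g == gg))
            mean[gg, j] = (2.0 ** gg) * p
            se[gg, j] = np.sqrt((4.0 ** gg) * p * (1 - p) / n)
    return params.n0 * mean, params.n0 * se


def timers_to_frame(clone_ids, timers_list) -> pd.DataFrame:
    """Long-form table of true vs observable timers for simulated clones.

    Columns: clone_id, variable, true_value, observed_flag,
    observed_value. The subsequent-division entry reports the first
    inter-division time; the destiny entry is proxied by the last
    realized division time under the observation rules.
    """
    rows = []
    for cid, timers in zip(clone_ids, timers_list):
        obs = apply_censoring(timers)
        for var, true_val, obs_val in [
                ("t_div0", timers.t_div0, obs.t_div0),
                ("m", timers.m_g[0] if timers.m_g else np.nan, obs.m),
                ("t_ld", timers.t_dd, obs.t_ld),
                ("t_die", timers.t_die, obs.t_die)]:
            rows.append((cid, var, true_val, obs_val is not None,
                         np.nan if obs_val is None else obs_val))
    return pd.DataFrame(rows, columns=["clone_id", "variable", "true_value",
                                       "observed_flag", "observed_value"])


def compare_with_mean_model(params: CytonParameters, times, n_families: int,
                            seed, max_generation: int = 8) -> float:
    """Max z-score between simulated and analytic per-generation means.

    Per (generation, time) cell the discrepancy |analytic - simulated| is
    scaled by the larger of the empirical Monte-Carlo standard error and
    the binomial standard error implied by the analytic occupancy
    probability (which covers cells where the simulation saw no families
    at all). Values below ~3 mean the simulator and the analytic
    expectations agree to Monte-Carlo accuracy.
    """
    from .mean_model import expected_timecourse
    times = np.asarray(times, dtype=float)
    mean, se = simulate_generation_counts(
        params, times, n_families, seed, max_generation=max_generation)
    tc = expected_timecourse(params, times, max_generation=max_generation,
                             truncation_tol=np.inf)
    gens = np.arange(max_generation + 1)[:, None]
    p_analytic = np.clip(tc.counts / (params.n0 * 2.0 ** gens), 0.0, 1.0)
    se_analytic = params.n0 * (2.0 ** gens) * np.sqrt(
        p_analytic * (1 - p_analytic) / n_families)
    scale = np.maximum.reduce([se, se_analytic,
                               np.full_like(se, 1e-12 * params.n0)])
    return float(np.max(np.abs(tc.counts - mean) / scale))


# ---------------------------------------------------------------------------
# censorship-induced correlation study

PAIR_NAMES = (
    ("t_div0", "m"), ("t_div0", "t_ld"), ("t_div0", "t_die"),
    ("m", "t_ld"), ("m", "t_die"), ("t_ld", "t_die"),
)


def censorship_study(dist_div0: TimerDistribution,
                     dist_sub: TimerDistribution,
                     dist_ld: TimerDistribution,
                     dist_die: TimerDistribution,
                     n_families: int, seed,
                     bf_subsample: Optional[int] = None) -> pd.DataFrame:
    """True-vs-observable correlation induced purely by right censoring.

    Four timers are sampled independently per family (the no-correlation
    construction; the last-division proxy is identified with the destiny
    time). The observation rules are applied, and for each of the six
    variable pairs the sample correlation and correlation Bayes factor are
    computed on the true values and on the observable subset. Because the
    underlying timers are independent, any H1-favouring Bayes factor on the
    observable side is censoring-induced.

    ``bf_subsample`` caps the number of pairs entering each Bayes-factor
    computation (deterministic head of the sampled families).
    """
    if n_families < 10:
        raise ValueError("need at least 10 families")
    rng = np.random.default_rng(seed)
    n = int(n_families)
    vals = {
        "t_div0": dist_div0.sample(n, rng),
        "m": dist_sub.sample(n, rng),
        "t_ld": dist_ld.sample(n, rng),  # destiny time; proxy identified
        "t_die": dist_die.sample(n, rng),
    }
    limit = np.minimum(vals["t_ld"], vals["t_die"])
    observed = {
        "t_div0": vals["t_div0"] < limit,
        "m": (vals["t_div0"] + vals["m"]) < limit,
        "t_ld": vals["t_ld"] <= vals["t_die"],
        "t_die": np.ones(n, dtype=bool),
    }
    rows = []
    for x, y in PAIR_NAMES:
        both = observed[x] & observed[y]
        n_obs = int(both.sum())
        if n_obs < 3:
            raise ValueError(
                f"pair ({x}, {y}) almost never observable "
                f"({n_obs}/{n}); distributions are degenerate for this study")
        xs, ys = vals[x], vals[y]
        xo, yo = xs[both], ys[both]
        if bf_subsample is not None:
            xs, ys = xs[:bf_subsample], ys[:bf_subsample]
            xo, yo = xo[:bf_subsample], yo[:bf_subsample]

        def corr(a, b):
            # zero-variance (e.g. point-mass timers) carries no
            # correlation evidence: score it as r = 0
            if np.std(a) == 0 or np.std(b) == 0:
                return 0.0
            return float(np.corrcoef(a, b)[0, 1])

        r_true = corr(xs, ys)
        r_obs = corr(xo, yo)
        bf10_t, bf01_t = bayes_factor_correlation(r_true, len(xs))
        bf10_o, bf01_o = bayes_factor_correlation(r_obs, len(xo))
        rows.append({
            "pair": f"({x}, {y})",
            "n_true": n, "n_obs": n_obs,
            "frac_obs": n_obs / n,
            "r_true": r_true, "r_obs": r_obs,
            "bf10_true": bf10_t, "bf01_true": bf01_t,
            "bf10_obs": bf10_o, "bf01_obs": bf01_o,
            "favoured_true": "H1" if bf10_t > 1 else "H0",
            "favoured_obs": "H1" if bf10_o > 1 else "H0",
        })
    return pd.DataFrame(rows)
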