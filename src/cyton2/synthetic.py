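"""Synthetic data generation emulating the two experimental input kinds.

Two generators, both fully seeded:

* :func:`synthesize_counts` — generation-structured cell counts as produced
  by a division-tracking (CFSE/CTV) flow-cytometry time course: the analytic
  expected count per generation at each harvest time, perturbed by
  multiplicative lognormal replicate noise, ``count = y_g(t) * exp(eps)``
  with ``eps ~ N(0, noise_sd^2)`` drawn independently per record.
* :func:`synthesize_trees` — clonal family trees from the agent-based
  simulator, in the lineage-table form produced by tracked microscopy.

Default study conditions follow the in-vitro assays the model was built
for: a 9-harvest x 3-replicate design over ~120 h, ~40 h median time to
first division, ~10 h subsequent divisions and 5% replicate noise; see the
methods note for the reasoning behind each default.
"""

from __future__ import annotations

import numpy as np

from .abm import simulate_family
from .distributions import make_distribution
from .mean_model import CytonParameters, expected_timecourse
from .trees import FamilyTree

__all__ = [
    "b_cell_like_parameters",
    "t_cell_like_parameters",
    "default_design",
    "synthesize_counts",
    "synthesize_trees",
]

#: harvest times (hours) of the standard 9-time-point design
DEFAULT_TIMES = (0.0, 24.0, 42.0, 54.0, 66.0, 78.0, 90.0, 108.0, 120.0)


def default_design() -> dict:
    return {"times": list(DEFAULT_TIMES), "replicates": 3, "noise_sd": 0.05}


def b_cell_like_parameters(n0: float = 1000.0) -> CytonParameters:
    """Lognormal timers resembling mitogen-stimulated B cells: late first
    division (~40 h median), ~10 h subsequent divisions, destiny well
    before a late, well-separated death time."""
    return CytonParameters(
        dist_div0=make_distribution("lognormal", m=40.0, s=0.2),
        subsequent=10.0,
        dist_dd=make_distribution("lognormal", m=60.0, s=0.25),
        dist_die=make_distribution("lognormal", m=100.0, s=0.3),
        n0=n0)


def t_cell_like_parameters(n0: float = 1000.0) -> CytonParameters:
    """Lognormal timers resembling weakly supported CD8+ T cells: slower
    subsequent divisions (~18 h) and strongly overlapping destiny and
    death distributions, so censoring is heavy."""
    return CytonParameters(
        dist_div0=make_distribution("lognormal", m=40.0, s=0.3),
        subsequent=18.0,
        dist_dd=make_distribution("lognormal", m=50.0, s=0.4),
        dist_die=make_distribution("lognormal", m=60.0, s=0.4),
        n0=n0)


def synthesize_counts(params: CytonParameters, times=None, replicates: int = 3,
                      noise_sd: float = 0.05, seed=0,
                      max_generation: int = 8):
    """Noisy generation-structured counts from the analytic mean model.

    Returns a :class:`~cyton2.fitting.GenerationCountTable`. With
    ``noise_sd=0`` the counts equal the expected values exactly.
    """
    from .fitting import GenerationCountTable
    import pandas as pd
    if times is None:
        times = DEFAULT_TIMES
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    tc = expected_timecourse(params, times, max_generation=max_generation,
                             truncation_tol=np.inf)
    rows = []
    for r in range(replicates):
        eps = rng.normal(0.0, noise_sd, size=tc.counts.shape) \
            if noise_sd > 0 else np.zeros_like(tc.counts)
        noisy = tc.counts * np.exp(eps)
        for j, t in enumerate(times):
            for g in range(max_generation + 1):
                rows.append((t, r, g, noisy[g, j]))
    frame = pd.DataFrame(rows, columns=["time_h", "replicate", "generation",
                                        "count"])
    return GenerationCountTable(frame)


def synthesize_trees(params: CytonParameters, n_families: int, seed=0,
                     max_generation: int = 12) -> list[FamilyTree]:
    """Simulated clonal family trees (one per founder)."""
    seeds = np.random.SeedSequence(seed).spawn(n_families)
    trees = []
    for i, ss in enumerate(seeds):
        tree, _ = simulate_family(params, np.random.default_rng(ss),
                                  max_generation=max_generation)
        tree.clone_id = f"clone-{i:05d}"
        trees.append(tree)
    return trees
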