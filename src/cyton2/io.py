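"""File formats: lineage-tree tables, generation-count tables, run configs.

Both data dialects are plain CSV with a leading ``#`` comment line that
records the units, so files are self-describing:

* tree tables — one row per cell: ``clone_id, cell_label, fate, time_h``
  where ``cell_label`` is the comma-joined lineage path (``""`` for the
  founder, e.g. ``"1,2,1"``) and ``fate`` is ``divided``/``died``/``lost``;
* count tables — one row per record: ``time_h, replicate, generation,
  count``.

Readers validate structural invariants (orphan cells, divided cells
without two daughters, duplicate count keys) and report offending clones
or keys in the error message.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import GenerationCountTable
from .mean_model import CytonParameters
from .trees import Cell, FamilyTree

__all__ = [
    "read_tree_table", "write_tree_table",
    "read_counts", "write_counts",
    "RunConfig", "read_config", "write_config",
    "generate_fixtures",
]

_TREE_COLUMNS = ("clone_id", "cell_label", "fate", "time_h")


def _label_to_str(label: tuple[int, ...]) -> str:
    return ",".join(str(x) for x in label)


def _str_to_label(s) -> tuple[int, ...]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return ()
    return tuple(int(x) for x in str(s).split(","))


def read_tree_table(path) -> list[FamilyTree]:
    """Read and validate a lineage-tree CSV into family trees."""
    frame = pd.read_csv(path, comment="#",
                        dtype={"clone_id": str, "cell_label": str},
                        keep_default_na=False,
                        float_precision="round_trip")
    missing = [c for c in _TREE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"tree table {path} missing columns {missing}")
    trees = []
    for clone_id, grp in frame.groupby("clone_id", sort=True):
        cells = [Cell(label=_str_to_label(row.cell_label), fate=row.fate,
                      fate_time=float(row.time_h))
                 for row in grp.itertuples()]
        trees.append(FamilyTree.from_cells(clone_id, cells))
    return trees


def write_tree_table(trees: Sequence[FamilyTree], path) -> None:
    rows = [(t.clone_id, _label_to_str(c.label), c.fate, c.fate_time)
            for t in trees for c in sorted(t.cells.values(),
                                           key=lambda c: c.label)]
    frame = pd.DataFrame(rows, columns=_TREE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# lineage tree table; time_h = hours from stimulation\n")
        frame.to_csv(fh, index=False)


def read_counts(path, condition: str = "") -> GenerationCountTable:
    """Read a generation-structured count CSV."""
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return GenerationCountTable(frame, condition=condition or Path(path).stem)


def write_counts(table: GenerationCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# generation-structured live-cell counts; "
                 "time_h = hours from stimulation\n")
        table.frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Serializable run options shared by the CLI commands."""

    seed: int
    model: Optional[dict] = None        # CytonParameters config block
    inputs: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    output_dir: str = "."

    def cyton_parameters(self) -> CytonParameters:
        if self.model is None:
            raise ValueError("config has no model block")
        return CytonParameters.from_config(self.model)

    def to_dict(self) -> dict:
        return asdict(self)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config must set a seed (stochastic commands "
                         "are required to be reproducible)")
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# fixture generation

def generate_fixtures(params: CytonParameters, out_dir, seed: int = 0,
                      times=None, replicates: int = 3,
                      noise_sd: float = 0.05, n_families: int = 50,
                      max_generation: int = 8) -> dict:
    """Write a matched pair of synthetic inputs plus a ground-truth sidecar.

    Produces ``trees.csv`` (agent-based family trees), ``counts.csv``
    (mean-model counts with multiplicative replicate noise) and
    ``truth.json`` recording the generating parameters, so recovery tests
    can compare estimates against the truth. Deterministic given ``seed``.
    """
    from .synthetic import synthesize_counts, synthesize_trees, DEFAULT_TIMES
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = list(times) if times is not None else list(DEFAULT_TIMES)
    trees = synthesize_trees(params, n_families=n_families, seed=seed)
    write_tree_table(trees, out / "trees.csv")
    counts = synthesize_counts(params, times=times, replicates=replicates,
                               noise_sd=noise_sd, seed=seed + 1,
                               max_generation=max_generation)
    write_counts(counts, out / "counts.csv")
    sidecar = {
        "parameters": params.to_config(),
        "design": {"times": times, "replicates": replicates,
                   "noise_sd": noise_sd, "n_families": n_families},
        "seed": seed,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
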