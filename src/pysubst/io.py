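"""File formats: partition configs (YAML), solution tables and expression
dumps, trajectory/scan TSV export, and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import sympy as sp
import yaml

from .model import MassActionModel
from .perturbation import Trajectory
from .substitution import PartitionMap, SteadyStateSolution

__all__ = [
    "load_partition_config",
    "solution_table",
    "write_solution_tsv",
    "write_expression_dump",
    "write_trajectory_tsv",
    "write_manifest",
]


def load_partition_config(path: str | Path, model: MassActionModel
                          ) -> tuple[PartitionMap, list[str] | None]:
    """Read a partition config: ordered ``Y:`` list, optional ``P:``,
    ``frozen:`` and ``independent_targets:`` lists."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "Y" not in cfg:
        raise ValueError("partition config needs at least an ordered 'Y:' list")
    pm = PartitionMap.from_sets(
        model, Y=list(cfg["Y"]), P=list(cfg["P"]) if "P" in cfg else None,
        frozen=frozenset(cfg.get("frozen", [])))
    targets = cfg.get("independent_targets")
    return pm, list(targets) if targets else None


def solution_table(solution: SteadyStateSolution) -> list[tuple[str, str, str]]:
    """Rows of (quantity, class, expression); class is one of
    ``P``, ``independent-Y``, ``dependent-Y``."""
    pm = solution.partition
    rows = []
    for name in pm.p_order:
        rows.append((name, "P", str(pm.quantity_symbol(name))))
    for name in pm.y_order:
        if pm.is_pseudo(name):
            continue
        sym = pm.quantity_symbol(name)
        if sym in solution.dependents:
            rows.append((name, "dependent-Y", str(solution.dependents[sym])))
        else:
            rows.append((name, "independent-Y", str(sym)))
    return rows


def write_solution_tsv(solution: SteadyStateSolution, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("quantity\tclass\texpression\n")
        for row in solution_table(solution):
            fh.write("\t".join(row) + "\n")


def write_expression_dump(solution: SteadyStateSolution, path: str | Path
                          ) -> None:
    """Machine-readable dump: sympy srepr strings keyed by quantity."""
    payload = {
        "branch_id": solution.branch_id,
        "independents": sorted(str(s) for s in solution.independents),
        "dependents": {str(k): sp.srepr(v)
                       for k, v in solution.dependents.items()},
        "verified": solution.verified,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_trajectory_tsv(traj: Trajectory, path: str | Path,
                         header_extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header_extra or {}).items():
            fh.write(f"# {k}: {v}\n")
        traj.to_frame().to_csv(fh, sep="\t", index=False)


def write_manifest(path: str | Path, inputs: dict, seed: int | None = None,
                   timings: dict | None = None) -> None:
    """Run manifest: inputs, package versions, seed and timings, enough to
    re-run the symbolic outputs bit-identically."""
    import numpy
    import scipy

    manifest = {
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": inputs,
        "seed": seed,
        "timings_s": timings or {},
        "versions": {
            "python": platform.python_version(),
            "sympy": sp.__version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
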