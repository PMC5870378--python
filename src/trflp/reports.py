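"""Presentation-layer exports: heatmap matrices and provenance records."""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .profiles import CommunityMatrix

__all__ = ["export_heatmap_matrix", "write_provenance"]


def export_heatmap_matrix(
    matrix: CommunityMatrix,
    ordering: str = "total_abundance",
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Bin × sample abundance table ordered for heatmap rendering.

    With ``ordering="total_abundance"`` rows (bins) are sorted by
    decreasing total abundance summed over samples — the convention that
    puts community dominants at the top of a fingerprint heatmap — with
    ties broken by ascending bin size; ``ordering="label"`` sorts by bin
    size instead.  A ``total`` companion column carries each bin's summed
    abundance.  The samples keep their matrix (metadata) order.
    """
    if not matrix.bin_labels:
        raise ValueError("cannot export an empty matrix")
    table = matrix.abundance.T.copy()  # bins × samples
    table.index.name = "bin"
    totals = table.sum(axis=1)
    sizes = np.array([float(lbl) for lbl in table.index])
    if ordering == "total_abundance":
        order = sorted(
            range(len(table)), key=lambda i: (-totals.iloc[i], sizes[i])
        )
    elif ordering == "label":
        order = sorted(range(len(table)), key=lambda i: sizes[i])
    else:
        raise ValueError("ordering must be 'total_abundance' or 'label'")
    table = table.iloc[order]
    table["total"] = totals.iloc[order]
    if path is not None:
        table.to_csv(path, sep="\t", float_format="%.10g")
    return table


def write_provenance(
    path: str | Path, config: Mapping[str, Any], seed: int | None
) -> dict[str, Any]:
    """Record configuration, seed and library versions next to run outputs."""
    from . import __version__

    record = {
        "config": {k: _jsonable(v) for k, v in config.items()},
        "seed": seed,
        "versions": {
            "trflp": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "argv": sys.argv,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    return record


def _jsonable(v: Any) -> Any:
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, Mapping):
        return {str(k): _jsonable(x) for k, x in v.items()}
    return str(v)
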