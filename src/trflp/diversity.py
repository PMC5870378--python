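"""Community diversity indices and core/shared/unique ribotype classes.

Each T-RF bin is treated as an operational taxon ("ribotype") and each
sample's relative-abundance vector p as a community composition.  Reported
per sample:

* richness S — number of bins with p_i > 0 (presence/absence);
* Shannon index H' = −Σ p_i ln p_i (natural log, in nats);
* Pielou evenness J' = H'/ln S (defined as 0 when S = 1);
* Simpson dominance D = Σ p_i², with both common diversity transforms,
  the complement 1 − D (bounded by 1 − 1/S) and the reciprocal 1/D.

Across host genotypes, detected ribotypes are classified as *core*
(present in every group), *unique* (one group only) or *shared* (some but
not all groups) — the fingerprinting analogue of a core microbiota.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import CommunityMatrix

__all__ = [
    "DiversitySummary",
    "RibotypeClassification",
    "diversity_indices",
    "diversity_table",
    "classify_trfs",
    "percent_unique",
]


@dataclass(frozen=True)
class DiversitySummary:
    richness: int
    shannon: float
    evenness: float
    simpson_complement: float
    simpson_reciprocal: float
    dominance: float


def diversity_indices(p: Sequence[float] | np.ndarray) -> DiversitySummary:
    """Diversity indices of one relative-abundance vector.

    The vector must already be a composition (entries ≥ 0 summing to 1
    within 1e-9); unnormalized input is rejected rather than silently
    rescaled, since a wrong total indicates an upstream processing error.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"abundances sum to {total!r}, not 1; not a composition")
    pos = p[p > 0]
    s = int(pos.size)
    shannon = float(-(pos * np.log(pos)).sum())
    evenness = float(shannon / np.log(s)) if s > 1 else 0.0
    d = float((pos**2).sum())
    return DiversitySummary(
        richness=s,
        shannon=shannon,
        evenness=evenness,
        simpson_complement=1.0 - d,
        simpson_reciprocal=1.0 / d,
        dominance=d,
    )


@dataclass(frozen=True)
class RibotypeClassification:
    """Partition of detected bins by group occupancy."""

    core: frozenset[str]
    shared: Mapping[str, frozenset[str]]  # bin -> groups (2 <= |groups| < all)
    unique: Mapping[str, frozenset[str]]  # group -> bins found only there


def classify_trfs(
    matrix: CommunityMatrix, grouping: Mapping[str, str]
) -> RibotypeClassification:
    """Classify each detected bin as core, shared or unique across groups.

    A bin counts as present in a group when its abundance exceeds 0 in at
    least one sample of that group.  Every sample in the matrix must be
    mapped to a group.
    """
    unmapped = [s for s in matrix.samples if s not in grouping]
    if unmapped:
        raise ValueError(f"samples without a group: {unmapped}")
    groups = sorted(set(grouping[s] for s in matrix.samples))

    presence: dict[str, set[str]] = {}
    for sample in matrix.samples:
        row = matrix.abundance.loc[sample]
        for lbl in matrix.bin_labels:
            if row[lbl] > 0:
                presence.setdefault(lbl, set()).add(grouping[sample])

    core, shared, unique = set(), {}, {g: set() for g in groups}
    for lbl, occ in presence.items():
        if len(occ) == len(groups):
            core.add(lbl)
        elif len(occ) == 1:
            unique[next(iter(occ))].add(lbl)
        else:
            shared[lbl] = frozenset(occ)
    return RibotypeClassification(
        core=frozenset(core),
        shared=shared,
        unique={g: frozenset(b) for g, b in unique.items()},
    )


def percent_unique(unique_count: int, total_count: int) -> float:
    """Percentage of a group's detected ribotypes that are genotype-specific.

    Reported to one decimal, matching how fingerprinting summaries print it.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= unique_count <= total_count:
        raise ValueError("unique_count must lie in [0, total_count]")
    return round(100.0 * unique_count / total_count, 1)


def diversity_table(
    matrix: CommunityMatrix,
    grouping: Mapping[str, str],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-group diversity summary: mean ± standard error over samples.

    Rows are (index, group); columns ``mean`` and ``se``.  When ``path`` is
    given the table is also written as TSV.
    """
    unmapped = [s for s in matrix.samples if s not in grouping]
    if unmapped:
        raise ValueError(f"samples without a group: {unmapped}")
    per_sample = {
        s: diversity_indices(matrix.abundance.loc[s].to_numpy())
        for s in matrix.samples
    }
    rows = []
    index_names = [
        ("richness", lambda d: d.richness),
        ("shannon", lambda d: d.shannon),
        ("evenness", lambda d: d.evenness),
        ("simpson_complement", lambda d: d.simpson_complement),
        ("simpson_reciprocal", lambda d: d.simpson_reciprocal),
    ]
    for group in sorted(set(grouping[s] for s in matrix.samples)):
        members = [s for s in matrix.samples if grouping[s] == group]
        for name, getter in index_names:
            vals = np.array([getter(per_sample[s]) for s in members], dtype=float)
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append(
                {"index": name, "group": group, "mean": float(vals.mean()), "se": se}
            )
    table = pd.DataFrame(rows).set_index(["index", "group"])
    if path is not None:
        table.to_csv(path, sep="\t", float_format="%.6g")
    return table
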