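"""Electropherogram peak processing: filtering, binning, normalization.

Fragment-analysis software (e.g. GeneMapper) exports one sized, quantified
peak per detected fragment.  Turning those per-run peak lists into a
cross-sample community table requires four steps, each exposed here:

1. :func:`read_peak_table` — ingest delimited peak exports;
2. :func:`filter_size_range` — keep peaks inside the size-standard range and
   below the organellar cutoff (host mitochondrial amplicons run ~850 bp,
   well above the ~730 bp bacterial product, so a length threshold removes
   them in silico);
3. :func:`bin_trfs` — align fragment sizes across samples into T-RF bins by
   single-linkage chaining, then normalize peak areas to relative abundance;
4. :func:`merge_replicates` — average duplicate instrument runs.

The result is a :class:`CommunityMatrix`: samples × T-RF bins, each row a
relative-abundance composition summing to 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakProfile",
    "TRFBin",
    "CommunityMatrix",
    "PeakTableFormatError",
    "read_peak_table",
    "write_peak_table",
    "filter_size_range",
    "normalize_profile",
    "bin_trfs",
    "merge_replicates",
    "community_matrix_from_profiles",
]


class PeakTableFormatError(ValueError):
    """A peak table is missing required columns or has malformed rows."""


@dataclass(frozen=True)
class Peak:
    sample_id: str
    enzyme: str
    size: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("peak size must be positive")
        if self.area <= 0:
            raise ValueError("peak area must be positive")


@dataclass(frozen=True)
class PeakProfile:
    """All peaks of one sample × enzyme × instrument run."""

    sample_id: str
    enzyme: str
    run_id: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.sample_id != self.sample_id or p.enzyme != self.enzyme:
                raise ValueError("peaks do not match profile sample/enzyme")


@dataclass(frozen=True)
class TRFBin:
    """One cross-sample T-RF: member (sample, size) pairs and their mean size."""

    representative_size: float
    members: tuple[tuple[str, float], ...] = ()

    @property
    def label(self) -> str:
        return f"{self.representative_size:.1f}"


@dataclass
class CommunityMatrix:
    """Samples × T-RF bins relative-abundance table.

    ``abundance`` rows sum to 1 (or are all zero for an empty sample);
    columns are keyed by bin label (mean member size, 1 decimal).
    """

    enzyme: str
    bins: tuple[TRFBin, ...]
    abundance: pd.DataFrame
    gap_tolerance: float = 0.5

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def bin_labels(self) -> list[str]:
        return list(self.abundance.columns)

    def __post_init__(self) -> None:
        sums = self.abundance.to_numpy().sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
        if not ok.all():
            bad = [s for s, o in zip(self.abundance.index, ok) if not o]
            raise ValueError(f"rows do not sum to 1: {bad}")

    def to_tsv(self, path_or_buf: str | Path | io.TextIOBase) -> None:
        """Write as TSV: first column the bin label, one column per sample."""
        table = self.abundance.T
        table.index.name = "bin"
        table.to_csv(path_or_buf, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path_or_buf: str | Path | io.TextIOBase, enzyme: str = "",
        gap_tolerance: float = 0.5,
    ) -> "CommunityMatrix":
        table = pd.read_csv(path_or_buf, sep="\t", index_col=0)
        bins = tuple(TRFBin(float(lbl)) for lbl in table.index)
        abundance = table.T
        abundance.columns = [b.label for b in bins]
        abundance.index = abundance.index.astype(str)
        return cls(enzyme, bins, abundance, gap_tolerance)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample", "enzyme", "size", "height", "area")


def read_peak_table(path: str | Path | io.TextIOBase, dialect: str | None = None) -> list[PeakProfile]:
    """Read a delimited peak table into per (sample, enzyme, run) profiles.

    Expects header columns ``sample, enzyme, size, height, area`` and
    optionally ``run`` (defaulting to a single run "1").  The delimiter is
    autodetected between comma and tab unless ``dialect`` gives one.
    """
    raw = pd.read_csv(
        path, sep=dialect if dialect else None, engine="python", dtype=str,
        skipinitialspace=True,
    )
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "dye" in raw.columns and "enzyme" not in raw.columns:
        raw = raw.rename(columns={"dye": "enzyme"})
    for col in _REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise PeakTableFormatError(f"peak table is missing column '{col}'")
    if "run" not in raw.columns:
        raw["run"] = "1"

    profiles: dict[tuple[str, str, str], list[Peak]] = {}
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            size, height, area = float(row.size), float(row.height), float(row.area)
        except (TypeError, ValueError) as exc:
            raise PeakTableFormatError(
                f"non-numeric size/height/area on data line {i + 1}"
            ) from exc
        key = (str(row.sample), str(row.enzyme), str(row.run))
        profiles.setdefault(key, []).append(
            Peak(key[0], key[1], size, height, area)
        )
    return [
        PeakProfile(s, e, r, tuple(peaks))
        for (s, e, r), peaks in profiles.items()
    ]


def write_peak_table(profiles: Iterable[PeakProfile], path: str | Path) -> None:
    """Write profiles back to the standard TSV dialect."""
    rows = [
        {
            "sample": pf.sample_id,
            "enzyme": pf.enzyme,
            "run": pf.run_id,
            "size": f"{p.size:.2f}",
            "height": f"{p.height:.1f}",
            "area": f"{p.area:.1f}",
        }
        for pf in profiles
        for p in pf.peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def filter_size_range(
    profile: PeakProfile,
    min_bp: float = 50.0,
    max_bp: float = 500.0,
    organellar_max: float = 800.0,
) -> PeakProfile:
    """Retain peaks inside the reliable sizing range (inclusive bounds).

    ``min_bp``/``max_bp`` default to the 50-500 bp window of a 500-size
    standard; ``organellar_max`` drops anything that could be a host
    organellar fragment (mitochondrial amplicons run ~850 bp).
    """
    if min_bp >= max_bp:
        raise ValueError("min_bp must be below max_bp")
    hi = min(max_bp, organellar_max)
    kept = tuple(p for p in profile.peaks if min_bp <= p.size <= hi)
    return PeakProfile(profile.sample_id, profile.enzyme, profile.run_id, kept)


def normalize_profile(profile: PeakProfile) -> np.ndarray:
    """Relative abundances p_i = area_i / Σ area_j, in peak order."""
    areas = np.array([p.area for p in profile.peaks], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("cannot normalize a profile with zero total area")
    return areas / total


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def _chain_bins(sizes: np.ndarray, gap_tolerance: float) -> np.ndarray:
    """Single-linkage chaining on sorted sizes: new bin where gap > tolerance.

    Returns, for sizes sorted ascending, the bin index of each element.
    """
    if sizes.size == 0:
        return np.zeros(0, dtype=int)
    gaps = np.diff(sizes)
    return np.concatenate([[0], np.cumsum(gaps > gap_tolerance)])


def bin_trfs(
    profiles: Sequence[PeakProfile], gap_tolerance: float = 0.5
) -> CommunityMatrix:
    """Align peak sizes across samples into T-RF bins and normalize.

    All profiles must come from the same enzyme digest.  Sizes are pooled,
    sorted, and chained: a new bin starts wherever the gap to the previous
    size exceeds ``gap_tolerance`` (sub-bp drift between runs keeps the same
    fragment connected).  Within a sample, areas falling in one bin are
    summed before row normalization.  Sample order follows first appearance.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be non-negative")
    enzymes = {pf.enzyme for pf in profiles}
    if len(enzymes) > 1:
        raise ValueError(f"profiles mix enzymes: {sorted(enzymes)}")
    enzyme = enzymes.pop() if enzymes else ""

    samples: list[str] = []
    entries: list[tuple[float, str, float]] = []  # (size, sample, area)
    for pf in profiles:
        if pf.sample_id not in samples:
            samples.append(pf.sample_id)
        for p in pf.peaks:
            entries.append((p.size, pf.sample_id, p.area))

    if not entries:
        abundance = pd.DataFrame(index=pd.Index(samples, dtype=str))
        return CommunityMatrix(enzyme, (), abundance, gap_tolerance)

    entries.sort(key=lambda t: t[0])
    sizes = np.array([e[0] for e in entries])
    assignment = _chain_bins(sizes, gap_tolerance)

    n_bins = assignment[-1] + 1
    bins = []
    for b in range(n_bins):
        member_idx = np.flatnonzero(assignment == b)
        members = tuple((entries[i][1], entries[i][0]) for i in member_idx)
        bins.append(TRFBin(float(sizes[member_idx].mean()), members))

    area = np.zeros((len(samples), n_bins))
    sample_pos = {s: i for i, s in enumerate(samples)}
    for (size, sample, a), b in zip(entries, assignment):
        area[sample_pos[sample], b] += a
    totals = area.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        rel = np.where(totals > 0, area / np.where(totals > 0, totals, 1.0), 0.0)

    abundance = pd.DataFrame(
        rel, index=pd.Index(samples, dtype=str), columns=[b.label for b in bins]
    )
    return CommunityMatrix(enzyme, tuple(bins), abundance, gap_tolerance)


def merge_replicates(
    matrices: Sequence[CommunityMatrix], how: str = "mean"
) -> CommunityMatrix:
    """Merge duplicate runs of the same samples into one matrix.

    The joint bin set is rebuilt by chaining the union of all runs' bins.
    With ``how="mean"`` (default) each sample's merged abundance is the
    arithmetic mean over runs, counting a bin absent from a run as 0, which
    damps run-to-run area noise.  With ``how="union"`` a bin's abundance is
    averaged only over the runs that detected it and the row renormalized,
    which preserves presence for richness at the cost of inflating rare
    bins.  Rows remain compositions either way.
    """
    if how not in {"mean", "union"}:
        raise ValueError("how must be 'mean' or 'union'")
    if not matrices:
        raise ValueError("need at least one matrix")
    enzymes = {m.enzyme for m in matrices}
    if len(enzymes) > 1:
        raise ValueError(f"matrices mix enzymes: {sorted(enzymes)}")
    sample_sets = {tuple(sorted(m.samples)) for m in matrices}
    if len(sample_sets) > 1:
        raise ValueError("matrices cover different sample sets")
    if len(matrices) == 1:
        return matrices[0]

    samples = matrices[0].samples
    tol = matrices[0].gap_tolerance

    # pool every member size of every run's bins (falling back to the bin
    # representative when member detail is absent, e.g. after TSV round
    # trips) and re-chain jointly: sub-bp drift between runs then reunites
    # fragments that a single sparse run split apart
    pooled: list[tuple[float, int, int, str]] = []  # (size, run, bin, sample)
    for r, m in enumerate(matrices):
        for j, b in enumerate(m.bins):
            if b.members:
                pooled.extend((z, r, j, s) for s, z in b.members)
            else:
                pooled.append((b.representative_size, r, j, ""))
    pooled.sort(key=lambda t: t[0])
    sizes_arr = np.array([t[0] for t in pooled])
    assignment = _chain_bins(sizes_arr, tol)
    n_bins = assignment[-1] + 1

    # every original (run, bin) lands in exactly one merged bin: chaining on
    # a superset of its members can only merge chains, never split them
    bin_of: dict[tuple[int, int], int] = {}
    for (z, r, j, s), b in zip(pooled, assignment):
        bin_of[(r, j)] = b

    merged_bins = []
    rel = np.zeros((len(samples), n_bins))
    seen = np.zeros((len(samples), n_bins))  # runs in which a bin was detected
    member_lists: list[list[tuple[str, float]]] = [[] for _ in range(n_bins)]
    size_lists: list[list[float]] = [[] for _ in range(n_bins)]
    for (z, r, j, s), b in zip(pooled, assignment):
        size_lists[b].append(z)
        if s:
            member_lists[b].append((s, z))
    for r, m in enumerate(matrices):
        for j in range(len(m.bins)):
            b = bin_of[(r, j)]
            col = m.abundance.iloc[:, j].reindex(samples).to_numpy()
            rel[:, b] += col
            seen[:, b] += (col > 0).astype(float)
    for b in range(n_bins):
        merged_bins.append(
            TRFBin(float(np.mean(size_lists[b])), tuple(member_lists[b]))
        )
    if how == "mean":
        rel /= len(matrices)
    else:  # union: average over detecting runs only, then renormalize rows
        rel = np.where(seen > 0, rel / np.where(seen > 0, seen, 1.0), 0.0)
        totals = rel.sum(axis=1, keepdims=True)
        rel = np.where(totals > 0, rel / np.where(totals > 0, totals, 1.0), 0.0)

    abundance = pd.DataFrame(
        rel, index=pd.Index(samples, dtype=str),
        columns=[b.label for b in merged_bins],
    )
    return CommunityMatrix(matrices[0].enzyme, tuple(merged_bins), abundance, tol)


def community_matrix_from_profiles(
    profiles: Sequence[PeakProfile],
    enzyme: str,
    gap_tolerance: float = 0.5,
    min_bp: float = 50.0,
    max_bp: float = 500.0,
    organellar_max: float = 800.0,
    min_abundance: float = 0.0,
    merge: str = "mean",
) -> CommunityMatrix:
    """Standard ingest path: filter, bin per run, merge runs.

    Profiles of other enzymes are ignored, so the full multi-enzyme peak
    table can be passed directly.  ``min_abundance`` optionally zeroes
    relative abundances below a floor (e.g. 0.005 for 0.5%) after merging,
    renormalizing the rows.
    """
    mine = [pf for pf in profiles if pf.enzyme == enzyme]
    if not mine:
        raise ValueError(f"no profiles for enzyme {enzyme!r}")
    runs = sorted({pf.run_id for pf in mine})
    per_run = []
    for run in runs:
        run_profiles = [
            filter_size_range(pf, min_bp, max_bp, organellar_max)
            for pf in mine
            if pf.run_id == run
        ]
        per_run.append(bin_trfs(run_profiles, gap_tolerance))
    matrix = merge_replicates(per_run, how=merge)
    if min_abundance > 0:
        rel = matrix.abundance.to_numpy()
        rel = np.where(rel >= min_abundance, rel, 0.0)
        totals = rel.sum(axis=1, keepdims=True)
        rel = np.where(totals > 0, rel / np.where(totals > 0, totals, 1.0), 0.0)
        abundance = pd.DataFrame(
            rel, index=matrix.abundance.index, columns=matrix.abundance.columns
        )
        matrix = CommunityMatrix(matrix.enzyme, matrix.bins, abundance, gap_tolerance)
    return matrix
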