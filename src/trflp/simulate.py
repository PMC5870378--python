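"""Synthetic T-RFLP scenarios with known community structure.

To validate the pipeline without deposited electropherograms, this module
fabricates everything the wet workflow would produce, with full knowledge of
the truth:

* 16S-like template sequences flanked by the 799f / 1492R priming sites,
  with one recognition site per enzyme planted at a chosen offset so every
  taxon has a known terminal fragment length;
* per-sample true abundance vectors: a log-normal base community (a few
  dominant ribotypes, a long tail, as fingerprinting heatmaps typically
  show) plus group-specific log-abundance shifts scaled by ``effect_size``
  and per-sample biological noise;
* noisy peak tables: peak area proportional to abundance with
  multiplicative log-normal noise, Gaussian sub-bp size-calling jitter,
  a detection floor, and duplicate instrument runs per sample.

Everything is deterministic given ``ScenarioConfig.seed``.

The default design mirrors a three-genotype greenhouse comparison (a
salt-sensitive, a moderately tolerant and a highly tolerant rice cultivar)
with three replicate seed samples each and duplicate runs per sample.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import (
    ENZYMES,
    PRIMERS,
    Amplicon,
    SequenceRecord,
    in_silico_pcr,
    predict_trf,
    reverse_complement,
)
from .profiles import Peak, PeakProfile, write_peak_table

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_scenario",
    "simulate_peak_tables",
]

# concrete expansions of the degenerate nested primers; any template built
# around them is matched exactly by the degenerate pair
_FWD = "AACAGGATTAGATACCCGG"  # 799f with M→A, K→G
_RCR = reverse_complement(PRIMERS["1492R"].sequence)

_BASES = np.array(list("ACGT"))
_SITE_PATTERNS = {
    "DdeI": re.compile("CT[ACGT]AG"),
    "HaeIII": re.compile("GGCC"),
    "HhaI": re.compile("GCGC"),
}
_CONCRETE_SITE = {"DdeI": "CTAAG", "HaeIII": "GGCC", "HhaI": "GCGC"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study design and noise levels for one synthetic scenario.

    Defaults emulate a three-genotype comparison with triplicate samples,
    duplicate runs, moderate multiplicative area noise (CV 0.3), sub-bp
    sizing jitter (SD 0.15 bp) and a detection floor of 50 area units on a
    50,000-unit total signal.
    """

    n_taxa: int = 20
    groups: tuple[tuple[str, int], ...] = (("IR29", 3), ("IC32", 3), ("IC37", 3))
    effect_size: float = 1.0
    area_cv: float = 0.3
    size_jitter_sd: float = 0.15
    detection_floor: float = 50.0
    n_replicate_runs: int = 2
    seed: int = 0
    enzymes: tuple[str, ...] = ("DdeI", "HaeIII", "HhaI")
    total_signal: float = 50_000.0
    base_sigma: float = 1.0  # SD of the base log-abundance profile
    sample_sigma: float = 0.3  # per-sample (biological replicate) log noise
    affected_fraction: float = 0.5  # share of taxa shifted per group
    insert_length: tuple[int, int] = (650, 750)
    trf_range: tuple[int, int] = (60, 495)
    trf_min_sep: int = 2
    flank_length: int = 25
    collision_pairs: int = 0  # taxon pairs sharing a T-RF in the first enzyme

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_replicate_runs < 1:
            raise ValueError("counts must be at least 1")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs at least one sample")
        if self.effect_size < 0 or self.size_jitter_sd < 0 or self.area_cv < 0:
            raise ValueError("noise scales must be non-negative")
        lo, hi = self.trf_range
        effective = self.n_taxa - self.collision_pairs
        if (hi - lo) < effective * self.trf_min_sep:
            raise ValueError(
                "trf_range too narrow to separate n_taxa fragments by trf_min_sep"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Everything knowable about a generated scenario."""

    config: ScenarioConfig
    records: tuple[SequenceRecord, ...]  # templates with flanks
    amplicons: tuple[Amplicon, ...]
    trf: Mapping[str, Mapping[str, int]]  # enzyme -> taxon id -> T-RF bp
    abundances: pd.DataFrame  # samples × taxa, rows sum to 1
    group_of: Mapping[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.index)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id} {rec.taxon}\n")
                for i in range(0, len(rec.sequence), 70):
                    fh.write(rec.sequence[i : i + 70] + "\n")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "trf": {e: dict(t) for e, t in self.trf.items()},
            "abundances": {
                s: self.abundances.loc[s].to_dict() for s in self.samples
            },
            "group_of": dict(self.group_of),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(4, size=length)])


def _scrub_sites(seq: list[str], rng: np.random.Generator) -> list[str]:
    """Mutate bases until no enzyme recognition site remains."""
    while True:
        s = "".join(seq)
        hits = [m for pat in _SITE_PATTERNS.values() for m in pat.finditer(s)]
        if not hits:
            return seq
        for m in hits:
            pos = m.start() + int(rng.integers(m.end() - m.start()))
            current = seq[pos]
            choices = [b for b in "ACGT" if b != current]
            seq[pos] = choices[int(rng.integers(3))]


def _draw_trf_targets(
    rng: np.random.Generator,
    cfg: ScenarioConfig,
    fixed: dict[str, list[int]] | None = None,
) -> dict[str, list[int]]:
    """Per enzyme, n_taxa T-RF lengths pairwise ≥ trf_min_sep apart
    (except deliberately colliding pairs in the first enzyme).

    Targets of *different* enzymes are kept ≥ 8 bp apart as well so the
    planted recognition sites never overlap within one amplicon.
    """
    lo, hi = cfg.trf_range
    cross_sep = max(cfg.trf_min_sep, 8)
    targets: dict[str, list[int]] = dict(fixed or {})
    for enzyme in cfg.enzymes:
        if enzyme in targets:
            continue
        chosen: list[int] = []
        for i in range(cfg.n_taxa):
            if enzyme == cfg.enzymes[0] and cfg.collision_pairs > 0:
                if 0 < i <= 2 * cfg.collision_pairs and i % 2 == 0:
                    chosen.append(chosen[i - 1])  # taxon pair shares a T-RF
                    continue
            same_taxon = [targets[e][i] for e in targets]
            for _ in range(10_000):
                cand = int(rng.integers(lo, hi + 1))
                if all(abs(cand - c) >= cfg.trf_min_sep for c in chosen) and all(
                    abs(cand - c) >= cross_sep for c in same_taxon
                ):
                    chosen.append(cand)
                    break
            else:
                raise ValueError("could not separate T-RF targets; widen trf_range")
        targets[enzyme] = chosen
    return targets


def _build_amplicon(
    rng: np.random.Generator,
    taxon_id: str,
    taxon: str,
    trfs: dict[str, int],
    cfg: ScenarioConfig,
) -> tuple[SequenceRecord, Amplicon]:
    """One template whose amplicon has the requested first-site offsets."""
    enzymes = [ENZYMES[e] for e in cfg.enzymes]
    for _ in range(200):
        insert_len = int(rng.integers(cfg.insert_length[0], cfg.insert_length[1] + 1))
        amp_len = len(_FWD) + insert_len + len(_RCR)
        # site intervals in amplicon coordinates; must be disjoint and inside
        # the insert
        intervals = []
        ok = True
        for enz in enzymes:
            start = trfs[enz.name] - enz.cut_offset
            stop = start + len(enz.site)
            if start < len(_FWD) or stop > amp_len - len(_RCR):
                ok = False
                break
            if any(start < s2 and s < stop for s, s2 in intervals):
                ok = False
                break
            intervals.append((start, stop))
        if not ok:
            continue

        insert = _scrub_sites(_random_seq(rng, insert_len), rng)
        amp = list(_FWD) + insert + list(_RCR)
        for enz, (start, _) in zip(enzymes, intervals):
            site = _CONCRETE_SITE[enz.name]
            amp[start : start + len(site)] = list(site)
        amp_seq = "".join(amp)

        flank5 = "".join(_random_seq(rng, cfg.flank_length))
        flank3 = "".join(_random_seq(rng, cfg.flank_length))
        record = SequenceRecord(taxon_id, flank5 + amp_seq + flank3, taxon=taxon)

        products = in_silico_pcr(record, PRIMERS["799f"], PRIMERS["1492R"])
        if len(products) != 1 or products[0].sequence != amp_seq:
            continue
        amplicon = products[0]
        if all(
            predict_trf(amplicon, enz).trf_length == trfs[enz.name]
            and predict_trf(amplicon, enz).cut_found
            for enz in enzymes
        ):
            return record, amplicon
    raise RuntimeError(f"failed to construct a valid template for {taxon_id}")


def _abundance_table(
    rng: np.random.Generator, cfg: ScenarioConfig, taxa: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    base = rng.normal(0.0, cfg.base_sigma, size=cfg.n_taxa)
    rows, index, group_of = [], [], {}
    for group, n_samples in cfg.groups:
        shift = np.zeros(cfg.n_taxa)
        if cfg.effect_size > 0:
            n_affected = max(1, round(cfg.affected_fraction * cfg.n_taxa))
            affected = rng.choice(cfg.n_taxa, size=n_affected, replace=False)
            shift[affected] = cfg.effect_size * rng.standard_normal(n_affected)
        for r in range(n_samples):
            log_a = base + shift + rng.normal(0.0, cfg.sample_sigma, cfg.n_taxa)
            a = np.exp(log_a)
            rows.append(a / a.sum())
            sample = f"{group}_{r + 1}"
            index.append(sample)
            group_of[sample] = group
    table = pd.DataFrame(rows, index=index, columns=list(taxa))
    return table, group_of


def generate_scenario(
    config: ScenarioConfig,
    trf_targets: Mapping[str, Sequence[int]] | None = None,
) -> GroundTruth:
    """Build templates, known T-RFs and true abundances for one scenario.

    Each taxon's template carries the forward and reverse priming sites
    around a 650-750 bp insert with exactly one planted recognition site per
    enzyme; inserts are otherwise scrubbed of recognition sites so the
    planted site is the terminal one.  With ``effect_size = 0`` all groups
    draw samples from the same abundance-generating distribution (the null
    scenario used for calibrating the ANOSIM test).

    ``trf_targets`` optionally fixes the planted T-RF length per enzyme and
    taxon (e.g. ``{"DdeI": [64, 240, 347, 355, 506]}``) instead of drawing
    them; unlisted enzymes are still drawn at random.
    """
    rng = np.random.default_rng([config.seed, 101])
    fixed = None
    if trf_targets is not None:
        for enzyme, given in trf_targets.items():
            if len(given) != config.n_taxa:
                raise ValueError("trf_targets must give one length per taxon")
        fixed = {e: [int(t) for t in v] for e, v in trf_targets.items()}
    targets = _draw_trf_targets(rng, config, fixed)
    taxa = [f"tax{i:02d}" for i in range(config.n_taxa)]

    records, amplicons = [], []
    for i, taxon_id in enumerate(taxa):
        per_taxon = {e: targets[e][i] for e in config.enzymes}
        rec, amp = _build_amplicon(rng, taxon_id, taxon_id, per_taxon, config)
        records.append(rec)
        amplicons.append(amp)

    trf = {
        e: {taxa[i]: targets[e][i] for i in range(config.n_taxa)}
        for e in config.enzymes
    }
    abund_rng = np.random.default_rng([config.seed, 202])
    abundances, group_of = _abundance_table(abund_rng, config, taxa)
    return GroundTruth(
        config=config,
        records=tuple(records),
        amplicons=tuple(amplicons),
        trf=trf,
        abundances=abundances,
        group_of=group_of,
    )


def simulate_peak_tables(
    truth: GroundTruth, path: str | Path | None = None
) -> list[PeakProfile]:
    """Render noisy peak profiles for every sample × enzyme × run.

    Peak area is ``total_signal × abundance`` times a mean-1 log-normal
    factor with coefficient of variation ``area_cv``; fragment size is the
    true T-RF plus Gaussian jitter; peaks below ``detection_floor`` are
    dropped (rare community members go undetected, as on a real
    instrument).  With ``path`` given, profiles are also written as a TSV
    peak table.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 303])
    sigma = float(np.sqrt(np.log1p(cfg.area_cv**2)))
    profiles = []
    for sample in truth.samples:
        p = truth.abundances.loc[sample].to_numpy()
        for enzyme in cfg.enzymes:
            trfs = np.array([truth.trf[enzyme][t] for t in truth.abundances.columns])
            for run in range(cfg.n_replicate_runs):
                if sigma > 0:
                    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=p.size)
                else:
                    noise = np.ones_like(p)
                areas = cfg.total_signal * p * noise
                sizes = trfs + rng.normal(0.0, cfg.size_jitter_sd, size=p.size)
                keep = areas >= cfg.detection_floor
                peaks = tuple(
                    Peak(sample, enzyme, float(s), float(0.6 * a), float(a))
                    for s, a in zip(sizes[keep], areas[keep])
                )
                profiles.append(PeakProfile(sample, enzyme, str(run + 1), peaks))
    if path is not None:
        write_peak_table(profiles, path)
    return profiles
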