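"""In-silico PCR and restriction digestion for T-RFLP and ARDRA prediction.

Terminal restriction fragment length polymorphism (T-RFLP) sizes only the
fluorescently labeled terminal fragment of each amplicon after digestion.
Predicting those terminal fragment (T-RF) lengths from reference 16S rRNA
sequences links observed electropherogram peaks back to taxa.  This module
performs the sequence-level half of that workflow:

* degenerate-primer in-silico PCR (:func:`in_silico_pcr`),
* labeled-end T-RF prediction (:func:`predict_trf`),
* full-digest ARDRA fingerprints (:func:`ardra_pattern`),
* matching observed fragment bins to predicted sizes (:func:`assign_identity`).

Primer matching is exact under IUPAC degeneracy: a degenerate code matches
any base in its set, and no mismatches are tolerated.  Restriction sites are
scanned on the top strand only; the enzymes shipped in :data:`ENZYMES`
(DdeI, HaeIII, HhaI) have degeneracy-palindromic sites, for which a
top-strand scan finds every double-stranded site.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Primer",
    "RestrictionEnzyme",
    "Amplicon",
    "TRFPrediction",
    "ARDRAPattern",
    "PRIMERS",
    "ENZYMES",
    "in_silico_pcr",
    "predict_trf",
    "ardra_pattern",
    "assign_identity",
    "read_fasta",
    "load_primers",
    "load_enzymes",
    "write_prediction_table",
    "reverse_complement",
]

# IUPAC nucleotide degeneracy codes and the base sets they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVN", "TGCAYRKMSWVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC codes included."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _validate_template(seq: str) -> str:
    s = seq.upper()
    if not s:
        raise ValueError("template sequence is empty")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(
            f"template contains non-ACGT characters {sorted(bad)}; "
            "ambiguity codes are not allowed in templates"
        )
    return s


def _validate_iupac(seq: str, what: str = "primer") -> str:
    s = seq.upper()
    if not s:
        raise ValueError(f"{what} sequence is empty")
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"{what} contains non-IUPAC characters {sorted(bad)}")
    return s


def _iupac_pattern(seq: str) -> re.Pattern[str]:
    """Compile a degenerate motif into a regex over {A,C,G,T}."""
    parts = []
    for code in seq:
        bases = sorted(IUPAC_SETS[code])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def _find_all(pattern: re.Pattern[str], text: str) -> list[int]:
    """All (possibly overlapping) match start positions."""
    hits, pos = [], 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


def _is_degenerate_palindrome(site: str) -> bool:
    rc = reverse_complement(site)
    if len(rc) != len(site):
        return False
    return all(IUPAC_SETS[a] == IUPAC_SETS[b] for a, b in zip(site, rc))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A reference DNA sequence (e.g. a 16S rRNA clone or isolate)."""

    id: str
    sequence: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_template(self.sequence))


@dataclass(frozen=True)
class Primer:
    """PCR primer; ``labeled`` marks the 5' fluorophore (e.g. 6FAM)."""

    name: str
    sequence: str
    labeled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_iupac(self.sequence))


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by its recognition site and cut geometry.

    ``cut_offset`` is the number of site bases retained on the 5' (labeled)
    fragment of the top strand, e.g. 1 for DdeI (C^TNAG).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", _validate_iupac(self.site, "site"))
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut_offset must lie within the recognition site")
        if not _is_degenerate_palindrome(self.site):
            warnings.warn(
                f"recognition site of {self.name} is not degeneracy-palindromic; "
                "top-strand scanning may miss bottom-strand sites",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Amplicon:
    """A PCR product located on its template (0-based, half-open)."""

    source_id: str
    start: int
    end: int
    sequence: str
    taxon: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("amplicon length does not match coordinates")


@dataclass(frozen=True)
class TRFPrediction:
    """Predicted labeled terminal fragment length for one amplicon/enzyme."""

    source_id: str
    enzyme: str
    trf_length: int
    cut_found: bool
    taxon: str | None = None


@dataclass(frozen=True)
class ARDRAPattern:
    """Full restriction fingerprint: fragment lengths, largest first."""

    source_id: str
    enzyme: str
    fragments: tuple[int, ...]

    def matches(self, other: "ARDRAPattern", tolerance: float = 0.0) -> bool:
        """Compare sorted fragment lists within a per-fragment size tolerance."""
        if len(self.fragments) != len(other.fragments):
            return False
        return all(
            abs(a - b) <= tolerance
            for a, b in zip(self.fragments, other.fragments)
        )


# ---------------------------------------------------------------------------
# shipped registries
# ---------------------------------------------------------------------------

#: Primers used for nested amplification of bacterial 16S rRNA from plant
#: tissue: a degenerate 27F in the first round, then the chloroplast-avoiding
#: 799f (5' 6FAM-labeled) with 1492R in the nested round.
PRIMERS: dict[str, Primer] = {
    "27F-Degen": Primer("27F-Degen", "AGRRTTYGATYMTGGYTYAG"),
    "799f": Primer("799f", "AACMGGATTAGATACCCKG", labeled=True),
    "1492R": Primer("1492R", "GGTTACCTTGTTACGACTT"),
}

#: REBASE cut geometries: DdeI C^TNAG, HaeIII GG^CC, HhaI GCG^C.
ENZYMES: dict[str, RestrictionEnzyme] = {
    "DdeI": RestrictionEnzyme("DdeI", "CTNAG", 1),
    "HaeIII": RestrictionEnzyme("HaeIII", "GGCC", 2),
    "HhaI": RestrictionEnzyme("HhaI", "GCGC", 3),
}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def in_silico_pcr(
    template: SequenceRecord, forward: Primer, reverse: Primer
) -> list[Amplicon]:
    """Locate all amplicons of a degenerate primer pair on a template.

    A forward match on the top strand pairs with the nearest downstream
    reverse-primer binding site (seen on the top strand as the reverse
    complement of the reverse primer).  Matching is exact under degeneracy.
    Amplicons are returned in template order; no match yields an empty list.
    """
    seq = template.sequence
    fwd_pat = _iupac_pattern(forward.sequence)
    rev_pat = _iupac_pattern(reverse_complement(reverse.sequence))
    fwd_hits = _find_all(fwd_pat, seq)
    rev_hits = _find_all(rev_pat, seq)
    rev_len = len(reverse.sequence)
    amplicons = []
    for f in fwd_hits:
        downstream = [r for r in rev_hits if r >= f + len(forward.sequence)]
        if not downstream:
            continue
        end = downstream[0] + rev_len
        amplicons.append(
            Amplicon(template.id, f, end, seq[f:end], taxon=template.taxon)
        )
    return amplicons


def predict_trf(
    amplicon: Amplicon,
    enzyme: RestrictionEnzyme,
    labeled_end: Literal["forward", "reverse"] = "forward",
) -> TRFPrediction:
    """Length of the labeled terminal fragment after digestion.

    The labeled strand is scanned 5'→3' for the first recognition-site
    occurrence; the fragment keeps ``cut_offset`` bases of the site.  An
    uncut amplicon yields its full length with ``cut_found=False``.
    """
    seq = amplicon.sequence
    if labeled_end == "reverse":
        seq = reverse_complement(seq)
    elif labeled_end != "forward":
        raise ValueError("labeled_end must be 'forward' or 'reverse'")
    m = _iupac_pattern(enzyme.site).search(seq)
    if m is None:
        return TRFPrediction(
            amplicon.source_id, enzyme.name, len(seq), False, amplicon.taxon
        )
    return TRFPrediction(
        amplicon.source_id,
        enzyme.name,
        m.start() + enzyme.cut_offset,
        True,
        amplicon.taxon,
    )


def ardra_pattern(amplicon: Amplicon, enzyme: RestrictionEnzyme) -> ARDRAPattern:
    """Full-digest fragment fingerprint (ARDRA) of an amplicon.

    Non-overlapping site occurrences are taken left to right; each cut falls
    ``cut_offset`` bases into its site.  Fragments partition the amplicon, so
    their lengths always sum to the amplicon length.
    """
    seq = amplicon.sequence
    pat = _iupac_pattern(enzyme.site)
    cuts, pos = [], 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            break
        cuts.append(m.start() + enzyme.cut_offset)
        pos = m.start() + len(enzyme.site)
    bounds = [0, *cuts, len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return ARDRAPattern(
        amplicon.source_id, enzyme.name, tuple(sorted(fragments, reverse=True))
    )


def assign_identity(
    bin_size: float,
    predictions: Sequence[TRFPrediction],
    tolerance: float = 1.0,
) -> list[str]:
    """Taxa whose predicted T-RF falls within ``tolerance`` bp of a bin.

    Several taxa can legitimately share one T-RF (e.g. distinct genera whose
    16S fragments co-migrate), so all matches are returned, ordered by
    closeness then alphabetically.  An empty list means the bin is
    unidentified.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    matches = [
        (abs(p.trf_length - bin_size), p.taxon)
        for p in predictions
        if p.taxon is not None and abs(p.trf_length - bin_size) <= tolerance
    ]
    return [taxon for _, taxon in sorted(matches, key=lambda t: (t[0], t[1]))]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read template sequences from a (multi-record, wrapped) FASTA file.

    The description after the first whitespace, when present, is kept as the
    taxon label.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        taxon = parts[1].strip() if len(parts) > 1 else None
        records.append(SequenceRecord(rec.id, str(rec.seq), taxon=taxon))
    return records


def load_primers(path: str | Path) -> dict[str, Primer]:
    """Load extra primers from tab-separated lines ``name  sequence  [labeled]``."""
    out = {}
    for row in _config_rows(path):
        labeled = len(row) > 2 and row[2].strip().lower() in {"1", "true", "labeled", "yes"}
        out[row[0]] = Primer(row[0], row[1], labeled=labeled)
    return out


def load_enzymes(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Load extra enzymes from tab-separated lines ``name  site  cut_offset``."""
    out = {}
    for row in _config_rows(path):
        out[row[0]] = RestrictionEnzyme(row[0], row[1], int(row[2]))
    return out


def _config_rows(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield line.split()


def write_prediction_table(
    predictions: Iterable[TRFPrediction], path: str | Path
) -> None:
    """Write predictions as TSV: source_id, taxon, enzyme, trf_length, cut_found."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source_id", "taxon", "enzyme", "trf_length", "cut_found"])
        for p in predictions:
            writer.writerow(
                [p.source_id, p.taxon or "", p.enzyme, p.trf_length, p.cut_found]
            )
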