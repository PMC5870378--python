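"""Brute-force oracles, independent of the package's scanning code.

Degenerate motifs are handled by exhaustively expanding every IUPAC code
into its concrete base set and testing plain string equality at every
offset — no regex, no shared helpers with the implementation.
"""

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT",
    "S": "CG", "W": "AT", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def expand(motif: str) -> list[str]:
    """Every concrete ACGT string a degenerate motif can match."""
    return ["".join(p) for p in product(*(IUPAC[c] for c in motif))]


def find_motif(template: str, motif: str) -> list[int]:
    """All start positions where any expansion of the motif occurs."""
    variants = set(expand(motif))
    w = len(motif)
    return [
        i for i in range(len(template) - w + 1) if template[i : i + w] in variants
    ]


def pcr_amplicons(template: str, forward: str, reverse: str) -> list[tuple[int, int]]:
    """(start, end) spans: each forward hit to nearest downstream reverse hit."""
    fwd_hits = find_motif(template, forward)
    rc_variants = {revcomp(v) for v in expand(reverse)}
    w = len(reverse)
    rev_hits = [
        i for i in range(len(template) - w + 1)
        if template[i : i + w] in rc_variants
    ]
    spans = []
    for f in fwd_hits:
        downstream = [r for r in rev_hits if r >= f + len(forward)]
        if downstream:
            spans.append((f, downstream[0] + w))
    return spans


def terminal_fragment(amplicon: str, site: str, cut_offset: int) -> tuple[int, bool]:
    """(labeled 5' fragment length, whether a site was found)."""
    hits = find_motif(amplicon, site)
    if not hits:
        return len(amplicon), False
    return hits[0] + cut_offset, True


def digest_fragments(amplicon: str, site: str, cut_offset: int) -> list[int]:
    """Fragment lengths from non-overlapping left-to-right site hits."""
    cuts, pos = [], 0
    variants = set(expand(site))
    w = len(site)
    while pos <= len(amplicon) - w:
        if amplicon[pos : pos + w] in variants:
            cuts.append(pos + cut_offset)
            pos += w
        else:
            pos += 1
    bounds = [0, *cuts, len(amplicon)]
    return sorted(
        (b - a for a, b in zip(bounds, bounds[1:]) if b > a), reverse=True
    )


def random_primered_template(rng, min_len=200, max_len=2000):
    """A random template with planted concrete 799f / rc(1492R) sites.

    Returns (template, forward_motif, reverse_motif).  Roughly half the
    calls plant a full primer pair; the rest are plain random sequence.
    """
    fwd, rev = "AACMGGATTAGATACCCKG", "GGTTACCTTGTTACGACTT"
    n = int(rng.integers(min_len, max_len + 1))
    bases = "ACGT"
    seq = [bases[i] for i in rng.integers(4, size=n)]
    if rng.random() < 0.5:
        f_concrete = expand(fwd)[int(rng.integers(len(expand(fwd))))]
        r_concrete = revcomp(rev)
        f_pos = int(rng.integers(0, max(1, n - 120)))
        r_pos = int(rng.integers(f_pos + len(f_concrete), n - len(r_concrete) + 1))
        seq[f_pos : f_pos + len(f_concrete)] = list(f_concrete)
        seq[r_pos : r_pos + len(r_concrete)] = list(r_concrete)
    return "".join(seq), fwd, rev
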