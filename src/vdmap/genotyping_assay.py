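"""In-silico restriction digestion for RFLP/dCAPS genotyping.

A point mutation that creates (or a dCAPS primer that engineers) a
restriction site lets alleles be scored on a gel by their digestion
fragment patterns.  This module matches IUPAC recognition patterns on the
given strand, cuts amplicons, and decides whether two alleles' fragment
patterns are distinguishable at a stated gel resolution.

Cut coordinates are 1-based: a cut "after position p" severs the backbone
between bases p and p+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: IUPAC recognition pattern and cut offset.

    ``cut_offset`` counts bases from the pattern start to the cut on the
    given strand; DdeI (C^TNAG) has recognition ``CTNAG`` and offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if any(b not in IUPAC for b in self.recognition.upper()):
            raise ValueError(f"{self.name}: invalid IUPAC pattern {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside pattern")

    def reverse_complement_pattern(self) -> str:
        return self.recognition.upper().translate(_COMPLEMENT)[::-1]


#: DdeI per standard enzyme tables: C^TNAG.
DDEI = EnzymeSpec("DdeI", "CTNAG", 1)


@dataclass(frozen=True)
class DigestResult:
    """Fragment-length multiset and cut positions for one digestion."""

    fragment_lengths: tuple[int, ...]  # sorted descending
    cut_positions: tuple[int, ...]


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _pattern_matches(seq: str, pattern: str) -> list[int]:
    """0-based start positions of all (overlapping) pattern matches."""
    pattern = pattern.upper()
    k = len(pattern)
    allowed = [IUPAC[b] for b in pattern]
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(seq[i + j] in allowed[j] for j in range(k))
    ]


def find_sites(
    seq: str, enzyme: EnzymeSpec, both_strands: bool = False
) -> list[int]:
    """1-based cut positions of all enzyme sites on the given strand.

    A match starting at 1-based position m cuts after position
    ``m + cut_offset - 1``.  Overlapping matches are all reported.  With
    ``both_strands`` the reverse-complement pattern is also searched and
    its cuts mapped back to top-strand coordinates.
    """
    seq = _check_sequence(seq)
    cuts = [m + enzyme.cut_offset for m in _pattern_matches(seq, enzyme.recognition)]
    if both_strands:
        rc_pattern = enzyme.reverse_complement_pattern()
        k = len(enzyme.recognition)
        # a bottom-strand cut cut_offset bases into the RC pattern lands
        # k - cut_offset bases into the top-strand match
        for m in _pattern_matches(seq, rc_pattern):
            cuts.append(m + (k - enzyme.cut_offset))
    return sorted(set(c for c in cuts if 0 < c < len(seq)))


def digest(seq: str, enzyme: EnzymeSpec, both_strands: bool = False) -> DigestResult:
    """Cut a sequence at every enzyme site; fragments sorted descending."""
    seq = _check_sequence(seq)
    cuts = find_sites(seq, enzyme, both_strands=both_strands)
    bounds = [0, *cuts, len(seq)]
    fragments = sorted(
        (b - a for a, b in zip(bounds, bounds[1:])), reverse=True
    )
    return DigestResult(tuple(fragments), tuple(cuts))


@dataclass(frozen=True)
class DigestDiff:
    """Per-allele fragment patterns and gel distinguishability."""

    wildtype: tuple[int, ...]
    mutant: tuple[int, ...]
    resolution: int
    distinguishable: bool


def allele_digest_diff(
    wt_amplicon: str,
    mut_amplicon: str,
    enzyme: EnzymeSpec,
    resolution: int = 10,
) -> DigestDiff:
    """Digest both alleles and ask whether a gel separates the patterns.

    The patterns are compared fragment-by-fragment after sorting
    descending (absent fragments count as length 0); the alleles are
    distinguishable iff some pair differs by at least ``resolution`` bp.
    """
    wt = digest(wt_amplicon, enzyme).fragment_lengths
    mut = digest(mut_amplicon, enzyme).fragment_lengths
    n = max(len(wt), len(mut))
    wt_p = wt + (0,) * (n - len(wt))
    mut_p = mut + (0,) * (n - len(mut))
    distinguishable = any(abs(a - b) >= resolution for a, b in zip(wt_p, mut_p))
    return DigestDiff(wt, mut, resolution, distinguishable)


def load_enzyme_table(path: str | Path | None = None) -> dict[str, EnzymeSpec]:
    """Load the enzyme TSV (name, recognition, cut_offset); the packaged
    table ships with DdeI."""
    if path is None:
        source = resources.files("vdmap.data").joinpath("enzymes.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    enzymes: dict[str, EnzymeSpec] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, recognition, offset = line.split("\t")[:3]
        enzymes[name] = EnzymeSpec(name, recognition, int(offset))
    return enzymes
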