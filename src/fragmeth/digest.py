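"""In-silico MspI digestion of a genome into size-selected analysis fragments.

MspI recognises CCGG and cuts between the first and second base (C^CGG).
Reduced-representation bisulfite libraries are built from the fragments
between consecutive MspI cuts, size-selected to enrich for CpG-dense DNA;
here the 40-220 bp size window is applied and the retained fragments serve
as the basic units of the differential-methylation analysis.

Coordinates are 0-based half-open throughout. CCGG is its own reverse
complement, so a forward-strand scan finds every site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

__all__ = ["Fragment", "find_ccgg_sites", "msp_fragments", "MSP_SITE"]

MSP_SITE = "CCGG"

# IUPAC nucleotide codes accepted in input sequences (uppercase only).
_IUPAC = set("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment: 0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fragment_id(self) -> str:
        return f"frag:{self.contig}:{self.start}-{self.end}"


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - _IUPAC
    if bad:
        raise ValueError(
            "sequence must be uppercase IUPAC nucleotides; "
            f"offending characters: {sorted(bad)!r}"
        )


def find_ccgg_sites(sequence: str) -> List[int]:
    """Return ascending 0-based start positions of every CCGG occurrence.

    Overlapping occurrences are all reported (CCGG cannot overlap itself,
    but the scan advances one base at a time regardless). N never matches.

    Raises
    ------
    ValueError
        If the sequence contains lowercase or non-IUPAC characters.
    """
    _validate_sequence(sequence)
    sites: List[int] = []
    pos = sequence.find(MSP_SITE)
    while pos != -1:
        sites.append(pos)
        pos = sequence.find(MSP_SITE, pos + 1)
    return sites


def msp_fragments(
    genome: Dict[str, str],
    min_len: int = 40,
    max_len: int = 220,
    include_terminal: bool = False,
) -> List[Fragment]:
    """Digest a genome at MspI sites and size-select the fragments.

    Cut coordinate is ``site + 1`` (C^CGG). Candidate fragments are the
    intervals between consecutive cuts on the same contig; the terminal
    segments (before the first cut, after the last cut) are excluded by
    default because they are not flanked by two cuts. Retained fragments
    satisfy ``min_len <= length <= max_len`` (both ends inclusive).

    Parameters
    ----------
    genome : mapping of contig name to uppercase sequence.
    min_len, max_len : inclusive size-selection bounds in bp.
    include_terminal : also emit the two terminal segments per contig.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must be <= max_len ({max_len})")
    fragments: List[Fragment] = []
    for contig, seq in genome.items():
        cuts = [p + 1 for p in find_ccgg_sites(seq)]
        if not cuts:
            continue
        bounds = cuts if not include_terminal else [0, *cuts, len(seq)]
        for start, end in zip(bounds[:-1], bounds[1:]):
            if min_len <= end - start <= max_len:
                fragments.append(Fragment(contig, start, end))
    return fragments
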