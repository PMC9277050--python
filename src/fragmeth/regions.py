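"""Analysis-unit construction: promoters, gene bodies, CpG islands, and
assignment of CpG sites to units.

Four unit kinds are used by the pipeline: MspI fragments (see
:mod:`fragmeth.digest`), promoters (a symmetric window around the TSS,
default +/-2000 bp), gene bodies (TSS to TES), and CpG islands (either an
externally supplied BED track, or detected with the classical
Gardiner-Garden rule: GC >= 50%, observed/expected CpG >= 0.6, >= 200 bp).

All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "AnalysisUnit",
    "UNIT_KINDS",
    "promoter_regions",
    "gene_body_regions",
    "detect_cgi",
    "assign_sites_to_units",
    "find_cpg_sites",
]

UNIT_KINDS = ("fragment", "promoter", "gene_body", "cgi")


@dataclass(frozen=True)
class GeneModel:
    """A gene as a TSS/TES pair; for '-' strand genes tss > tes."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: '+' strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: '-' strand requires tss > tes")


@dataclass(frozen=True)
class AnalysisUnit:
    """A genomic interval acting as one row of the methylation matrix."""

    unit_id: str
    contig: str
    start: int
    end: int
    kind: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"unit {self.unit_id}: start must be < end")
        if self.kind not in UNIT_KINDS:
            raise ValueError(f"unit {self.unit_id}: unknown kind {self.kind!r}")
        if self.kind in ("promoter", "gene_body") and self.gene_id is None:
            raise ValueError(f"unit {self.unit_id}: {self.kind} units need a gene_id")

    @property
    def length(self) -> int:
        return self.end - self.start


def _contig_length(contig_lengths: Mapping[str, int], gene: GeneModel) -> int:
    try:
        return contig_lengths[gene.contig]
    except KeyError:
        raise KeyError(
            f"gene {gene.gene_id} lies on contig {gene.contig!r} "
            "absent from the genome"
        ) from None


def promoter_regions(
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    flank: int = 2000,
) -> List[AnalysisUnit]:
    """Symmetric promoter windows [tss - flank, tss + flank), clipped to the
    contig. Strand enters only through which coordinate is the TSS."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    units = []
    for g in genes:
        clen = _contig_length(contig_lengths, g)
        start = max(0, g.tss - flank)
        end = min(clen, g.tss + flank)
        units.append(
            AnalysisUnit(f"prom:{g.gene_id}", g.contig, start, end, "promoter", g.gene_id)
        )
    return units


def gene_body_regions(
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
) -> List[AnalysisUnit]:
    """Gene-body units spanning min(tss, tes) to max(tss, tes), half-open."""
    units = []
    for g in genes:
        _contig_length(contig_lengths, g)
        start, end = min(g.tss, g.tes), max(g.tss, g.tes)
        units.append(
            AnalysisUnit(f"body:{g.gene_id}", g.contig, start, end, "gene_body", g.gene_id)
        )
    return units


def detect_cgi(
    sequence: str,
    contig: str = "contig",
    window: int = 200,
    gc_min: float = 0.50,
    oe_min: float = 0.60,
    min_len: int = 200,
) -> List[AnalysisUnit]:
    """Detect CpG islands with a sliding-window Gardiner-Garden rule.

    Every window of ``window`` bp (stepped by 1) with GC fraction >= gc_min
    and observed/expected CpG = (nCpG * L) / (nC * nG) >= oe_min qualifies;
    overlapping qualifying windows are merged and merged runs shorter than
    ``min_len`` are dropped.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    n = len(sequence)
    if n < window:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def windowed(x: np.ndarray, w: int) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[w:] - cs[:-w]

    nc = windowed(is_c, window)
    ng = windowed(is_g, window)
    # CpG dinucleotides fully inside the window: starts in [i, i+window-1)
    ncpg = windowed(is_cpg, window - 1)[: n - window + 1] if window > 1 else is_cpg
    gc = (nc + ng) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((nc > 0) & (ng > 0), ncpg * window / np.maximum(nc * ng, 1), 0.0)
    ok = (gc >= gc_min) & (oe >= oe_min)

    units: List[AnalysisUnit] = []
    starts = np.flatnonzero(ok)
    if starts.size == 0:
        return []
    # merge window intervals [s, s+window) for consecutive qualifying starts
    run_start = starts[0]
    prev = starts[0]
    runs = []
    for s in starts[1:]:
        if s <= prev + window:  # windows overlap or touch
            prev = s
        else:
            runs.append((run_start, prev + window))
            run_start = prev = s
    runs.append((run_start, prev + window))
    for s, e in runs:
        if e - s >= min_len:
            units.append(
                AnalysisUnit(f"cgi:{contig}:{s}-{e}", contig, int(s), int(e), "cgi")
            )
    return units


def find_cpg_sites(sequence: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide (forward strand)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def assign_sites_to_units(
    sites: Mapping[str, Sequence[int]] | Sequence[int],
    units: Sequence[AnalysisUnit],
    contig: Optional[str] = None,
) -> Dict[str, np.ndarray]:
    """Map each unit_id to the sorted site positions falling inside it.

    A site at position p belongs to unit [s, e) iff s <= p < e; sites may
    belong to several overlapping units (a fragment inside a promoter, say).

    ``sites`` is either a mapping contig -> positions, or a plain sequence of
    positions together with ``contig``.
    """
    if not isinstance(sites, Mapping):
        if contig is None:
            raise ValueError("contig required when sites is a flat sequence")
        sites = {contig: sites}
    by_contig = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in sites.items()}
    out: Dict[str, np.ndarray] = {}
    for u in units:
        pos = by_contig.get(u.contig)
        if pos is None or pos.size == 0:
            out[u.unit_id] = np.empty(0, dtype=np.int64)
            continue
        lo = np.searchsorted(pos, u.start, side="left")
        hi = np.searchsorted(pos, u.end, side="left")
        out[u.unit_id] = pos[lo:hi]
    return out
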