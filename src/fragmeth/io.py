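"""Readers and writers for the pipeline's external formats, and the run
configuration.

Conventions at the boundary:

* FASTA — contig name is the first whitespace token after ``>``; sequence is
  uppercased on load; duplicate names are an error.
* Coverage files (Bismark coverage dialect) — six tab-separated columns:
  contig, start, end, methylation%, count_methylated, count_unmethylated,
  1-based inclusive with start == end at the C of the CpG. Internally
  everything is 0-based half-open; the percent column is recomputed from the
  counts (a discrepancy beyond 0.1 points is logged, counts win).
* Gene models — TSV with columns gene_id, contig, strand, tss, tes (0-based).
* Intervals — BED (0-based half-open) for CGI tracks and fragments.
* Everything tabular — TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .digest import Fragment
from .regions import AnalysisUnit, GeneModel

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "read_coverage",
    "write_coverage",
    "read_gene_models",
    "write_gene_models",
    "read_bed_units",
    "write_bed_units",
    "write_fragments_bed",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_unit_catalog",
    "write_unit_catalog",
    "read_clinical",
    "write_clinical",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run; round-trips through YAML."""

    schema_version: int = 1
    min_fragment_len: int = 40
    max_fragment_len: int = 220
    promoter_flank: int = 2000
    min_cov: int = 5
    min_sites: int = 1
    p_thr: float = 0.05
    q_thr: float = 0.05
    diff_thr: float = 0.25
    unit_test: str = "ttest"  # or "fisher"
    continuous_test: str = "mannwhitney"  # or "ttest"
    cutoff_sd_ddof: int = 1  # 1 = sample SD, 0 = population SD
    cox_ties: str = "efron"  # or "breslow"
    entry_p: float = 0.200
    seed: int = 0
    out_dir: str = "fragmeth_out"

    def __post_init__(self) -> None:
        if not 0 < self.min_fragment_len <= self.max_fragment_len:
            raise ValueError("invalid fragment size bounds")
        if self.promoter_flank <= 0:
            raise ValueError("promoter_flank must be positive")
        for name in ("p_thr", "q_thr", "diff_thr", "entry_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.unit_test not in ("ttest", "fisher"):
            raise ValueError("unit_test must be 'ttest' or 'fisher'")
        if self.continuous_test not in ("mannwhitney", "ttest"):
            raise ValueError("continuous_test must be 'mannwhitney' or 'ttest'")
        if self.cox_ties not in ("efron", "breslow"):
            raise ValueError("cox_ties must be 'efron' or 'breslow'")
        if self.cutoff_sd_ddof not in (0, 1):
            raise ValueError("cutoff_sd_ddof must be 0 or 1")

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"malformed config file {path}")
        return cls(**data)


# ---------------------------------------------------------------- FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------- coverage

_COV_COLS = ["contig", "start", "end", "pct", "meth", "unmeth"]


def read_coverage(path: PathLike, one_based: bool = True) -> pd.DataFrame:
    """Read a Bismark-coverage-style TSV into (contig, pos, meth, unmeth).

    Positions are converted to 0-based. The percent column is checked
    against the counts; counts win (a mismatch beyond 0.1 points warns).
    An empty file yields an empty callset with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLS,
                         dtype={"contig": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_COV_COLS)
    if df.empty:
        logger.warning("coverage file %s is empty", path)
        return pd.DataFrame(columns=["contig", "pos", "meth", "unmeth"])
    for col in ("start", "end", "meth", "unmeth"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric column {col!r} in {path}")
    if (df[["meth", "unmeth"]] < 0).to_numpy().any():
        raise ValueError(f"negative counts in {path}")
    total = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * df["meth"] / total, 0.0)
    if np.nanmax(np.abs(pct - df["pct"].to_numpy())) > 0.1:
        logger.warning(
            "methylation%% column in %s inconsistent with counts; counts win", path
        )
    pos = df["start"].astype(np.int64) - (1 if one_based else 0)
    return pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": pos,
            "meth": df["meth"].astype(np.int64),
            "unmeth": df["unmeth"].astype(np.int64),
        }
    )


def write_coverage(calls: pd.DataFrame, path: PathLike, one_based: bool = True) -> None:
    """Write (contig, pos, meth, unmeth) rows as a Bismark-style coverage TSV."""
    total = calls["meth"] + calls["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * calls["meth"] / total, 0.0)
    start = calls["pos"] + (1 if one_based else 0)
    out = pd.DataFrame(
        {
            "contig": calls["contig"],
            "start": start,
            "end": start,
            "pct": np.round(pct, 6),
            "meth": calls["meth"],
            "unmeth": calls["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------- genes, intervals


def read_gene_models(path: PathLike) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    required = {"gene_id", "contig", "strand", "tss", "tes"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene-model file {path} must have columns {sorted(required)}")
    return [
        GeneModel(r.gene_id, r.contig, r.strand, int(r.tss), int(r.tes))
        for r in df.itertuples(index=False)
    ]


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "contig": g.contig, "strand": g.strand,
             "tss": g.tss, "tes": g.tes}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_bed_units(path: PathLike, kind: str = "cgi") -> List[AnalysisUnit]:
    """Load a BED track verbatim as analysis units of the given kind."""
    units = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            uid = name or f"{kind}:{contig}:{start}-{end}"
            units.append(AnalysisUnit(uid, contig, start, end, kind))
    return units


def write_bed_units(units: Sequence[AnalysisUnit], path: PathLike) -> None:
    with open(path, "w") as fh:
        for u in units:
            fh.write(f"{u.contig}\t{u.start}\t{u.end}\t{u.unit_id}\t0\t+\n")


def write_fragments_bed(fragments: Sequence[Fragment], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.fragment_id}\n")


# ------------------------------------------------- samples, units, clinic


def read_sample_sheet(path: PathLike) -> Dict[str, str]:
    """TSV (sample_id, group) -> mapping; groups must be case/control."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError(f"sample sheet {path} needs columns sample_id, group")
    groups = dict(zip(df["sample_id"], df["group"]))
    bad = set(groups.values()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)} in {path}")
    return groups


def write_sample_sheet(groups: Mapping[str, str], path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_unit_catalog(path: PathLike) -> List[AnalysisUnit]:
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str, "contig": str})
    units = []
    for r in df.itertuples(index=False):
        gene = r.gene_id if isinstance(r.gene_id, str) and r.gene_id else None
        units.append(AnalysisUnit(r.unit_id, r.contig, int(r.start), int(r.end),
                                  r.kind, gene))
    return units


def write_unit_catalog(units: Sequence[AnalysisUnit], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"unit_id": u.unit_id, "contig": u.contig, "start": u.start,
             "end": u.end, "kind": u.kind,
             "gene_id": u.gene_id if u.gene_id else ""}
            for u in units
        ]
    ).to_csv(path, sep="\t", index=False)


def read_clinical(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clinical(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)
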