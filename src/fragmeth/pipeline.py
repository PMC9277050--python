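"""End-to-end composition: digest -> regions -> differential methylation ->
candidate genes, with optional clinical and survival stages, plus a run
manifest that records everything needed to reproduce the run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .candidates import annotate_dmfs, candidate_table, select_candidates
from .clinstats import compare_groups
from .diffmeth import call_dmf, dmf_table, global_methylation, unit_methylation
from .digest import msp_fragments
from .io import (
    PipelineConfig,
    read_bed_units,
    read_clinical,
    read_coverage,
    read_fasta,
    read_gene_models,
    read_sample_sheet,
    write_fragments_bed,
    write_unit_catalog,
)
from .regions import AnalysisUnit, detect_cgi, gene_body_regions, promoter_regions
from .survival import multivariate_selection

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """File-system inputs of one run."""

    fasta: Path
    gene_models: Path
    sample_sheet: Path
    coverage_dir: Path  # one <sample_id>.cov TSV per sample
    cgi_bed: Optional[Path] = None
    clinical: Optional[Path] = None


@dataclass
class PipelineResult:
    fragments_bed: Path
    unit_catalog: Path
    dmf_tsv: Path
    candidates_tsv: Path
    manifest: Path
    clinstats_tsv: Optional[Path] = None
    survival_tsv: Optional[Path] = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    """Execute the full fragment-methylation pipeline and write all outputs.

    Stages: MspI digestion and size selection; promoter / gene-body / CGI
    unit construction; unit-level aggregation of the per-sample coverage
    files; DMF calling under the triple threshold; promoter-based candidate
    gene selection; optionally clinical group comparison and Cox survival
    modelling when a clinical table is supplied. Raises on the first failing
    stage with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "digest"
    try:
        genome = read_fasta(inputs.fasta)
        contig_lengths = {c: len(s) for c, s in genome.items()}
        fragments = msp_fragments(
            genome, config.min_fragment_len, config.max_fragment_len
        )
        frag_units = [
            AnalysisUnit(f.fragment_id, f.contig, f.start, f.end, "fragment")
            for f in fragments
        ]
        logger.info("digest: %d size-selected fragments", len(frag_units))

        stage = "regions"
        genes = read_gene_models(inputs.gene_models)
        promoters = promoter_regions(genes, contig_lengths, config.promoter_flank)
        bodies = gene_body_regions(genes, contig_lengths)
        if inputs.cgi_bed is not None:
            cgis = read_bed_units(inputs.cgi_bed, kind="cgi")
        else:
            cgis = [
                u for c, s in genome.items() for u in detect_cgi(s, contig=c)
            ]
        units = frag_units + promoters + bodies + cgis
        logger.info(
            "regions: %d promoters, %d gene bodies, %d CGIs",
            len(promoters), len(bodies), len(cgis),
        )

        stage = "diffmeth"
        groups = read_sample_sheet(inputs.sample_sheet)
        calls = {}
        for sample in groups:
            cov = Path(inputs.coverage_dir) / f"{sample}.cov"
            if not cov.exists():
                raise FileNotFoundError(f"coverage file missing for {sample}: {cov}")
            calls[sample] = read_coverage(cov)
        matrix = unit_methylation(calls, units, config.min_cov, config.min_sites)
        records = call_dmf(
            matrix, groups,
            p_thr=config.p_thr, q_thr=config.q_thr, diff_thr=config.diff_thr,
            test=config.unit_test,
        )
        glob = global_methylation(calls, config.min_cov)
        logger.info(
            "diffmeth: %d tested units, %d hyper, %d hypo",
            len(records),
            sum(r.status == "hyper" for r in records),
            sum(r.status == "hypo" for r in records),
        )

        stage = "candidates"
        annotated = annotate_dmfs(records, matrix.units, promoters, bodies, cgis)
        cands = select_candidates(annotated)
        logger.info("candidates: %d promoter-associated genes", len(cands))
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    frag_bed = out / "fragments.bed"
    write_fragments_bed(fragments, frag_bed)
    catalog = out / "units.tsv"
    write_unit_catalog(units, catalog)
    dmf_path = out / "dmf.tsv"
    dmf_table(records).to_csv(dmf_path, sep="\t", index=False)
    cand_path = out / "candidates.tsv"
    candidate_table(cands).to_csv(cand_path, sep="\t", index=False)
    glob.to_frame().to_csv(out / "global_methylation.tsv", sep="\t")

    clin_path = surv_path = None
    if inputs.clinical is not None:
        stage = "clinstats"
        try:
            clin = read_clinical(inputs.clinical)
            rows = []
            for col in clin.columns:
                if col in (
                    "patient_id", "hypermethylated", "os_time", "os_event",
                    "lfs_time", "lfs_event",
                ):
                    continue
                kind = (
                    "continuous"
                    if pd.api.types.is_float_dtype(clin[col])
                    else "categorical"
                )
                try:
                    res = compare_groups(
                        clin, col, kind, continuous_test=config.continuous_test
                    )
                except (ValueError, KeyError) as e:
                    logger.warning("skipping variable %s: %s", col, e)
                    continue
                rows.append(
                    {"variable": res.variable, "test": res.test, "p": res.p_value,
                     "summary": res.summary or ""}
                )
            clin_path = out / "clinstats.tsv"
            pd.DataFrame(rows).to_csv(clin_path, sep="\t", index=False)

            stage = "survival"
            covs = [
                c for c in clin.columns
                if c not in ("patient_id", "os_time", "os_event",
                             "lfs_time", "lfs_event", "methylation_value")
            ]
            uni, multi, selected = multivariate_selection(
                clin, covs, "os_time", "os_event",
                entry_p=config.entry_p, ties=config.cox_ties,
            )
            rows = []
            for c in covs:
                u = uni[c]
                row = {
                    "variable": c,
                    "uni_hr": u.hazard_ratio[0],
                    "uni_ci": f"{u.ci_low[0]:.3f}-{u.ci_high[0]:.3f}",
                    "uni_p": u.p_value[0],
                    "multi_hr": "", "multi_ci": "", "multi_p": "",
                }
                if multi is not None and c in selected:
                    i = selected.index(c)
                    row.update(
                        multi_hr=multi.hazard_ratio[i],
                        multi_ci=f"{multi.ci_low[i]:.3f}-{multi.ci_high[i]:.3f}",
                        multi_p=multi.p_value[i],
                    )
                rows.append(row)
            surv_path = out / "survival.tsv"
            pd.DataFrame(rows).to_csv(surv_path, sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest_path = out / "manifest.json"
    config_dict = dataclasses.asdict(config)
    input_files = {
        "fasta": inputs.fasta,
        "gene_models": inputs.gene_models,
        "sample_sheet": inputs.sample_sheet,
    }
    if inputs.cgi_bed:
        input_files["cgi_bed"] = inputs.cgi_bed
    if inputs.clinical:
        input_files["clinical"] = inputs.clinical
    manifest = {
        "fragmeth_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "input_sha256": {k: _sha256(Path(v)) for k, v in input_files.items()},
        "row_counts": {
            "fragments": len(fragments),
            "units": len(units),
            "tested_units": len(records),
            "dmf_hyper": sum(r.status == "hyper" for r in records),
            "dmf_hypo": sum(r.status == "hypo" for r in records),
            "candidates": len(cands),
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        fragments_bed=frag_bed,
        unit_catalog=catalog,
        dmf_tsv=dmf_path,
        candidates_tsv=cand_path,
        manifest=manifest_path,
        clinstats_tsv=clin_path,
        survival_tsv=surv_path,
    )
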