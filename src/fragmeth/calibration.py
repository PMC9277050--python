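"""Simulation studies of the pipeline's operating characteristics.

These drive both the test suite and the reproducibility script: false-call
rate of DMF calling on null data, sensitivity and direction agreement on
planted effects, candidate-gene recovery, and Cox coefficient recovery.
Each study runs the full relevant slice of the pipeline on freshly
generated synthetic data; nothing is cached or precomputed.

Problem sizes follow the design the generators emulate: a 5-case / 4-control
methylome at ~30x depth with beta-binomial dispersion 0.1, around 1,600
fragment units of which 220 carry planted +/-0.4 shifts, and survival
cohorts of 1,000 patients with a log-hazard of 0.7 on the binary marker.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .candidates import annotate_dmfs, select_candidates
from .diffmeth import call_dmf, unit_methylation
from .digest import msp_fragments
from .regions import AnalysisUnit, gene_body_regions, promoter_regions
from .survival import cox_fit
from .synthdata import (
    SimDesign,
    SurvivalSimDesign,
    simulate_clinical,
    simulate_genome,
    simulate_methylome,
)

__all__ = ["dmf_operating_characteristics", "candidate_recovery", "cox_recovery"]


def _fragment_units(genome) -> List[AnalysisUnit]:
    return [
        AnalysisUnit(f.fragment_id, f.contig, f.start, f.end, "fragment")
        for f in msp_fragments(genome.contigs)
    ]


def dmf_operating_characteristics(
    seed: int,
    n_planted: int = 220,
    delta: float = 0.4,
) -> Dict[str, float]:
    """Null false-call rate and planted-effect sensitivity of DMF calling.

    Two methylomes are simulated on the same ~1,600-fragment genome: one with
    no effects (every q < 0.05 call is false) and one with ``n_planted``
    fragments shifted by +/-``delta``. Returns the null q < 0.05 rate, the
    sensitivity (fraction of planted, tested units called with any
    direction), the direction agreement among detected units, and the
    problem sizes.
    """
    genome = simulate_genome(
        n_contigs=2, contig_len=120_000, ccgg_rate=0.012, n_genes=10, seed=seed
    )
    units = _fragment_units(genome)

    null_design = SimDesign(seed=seed + 1)
    calls, _ = simulate_methylome(genome, units, null_design)
    matrix = unit_methylation(calls, units)
    records = call_dmf(matrix, null_design.groups)
    n_null = len(records)
    null_rate = float(np.mean([r.q_value < 0.05 for r in records]))

    rng = np.random.default_rng(seed + 2)
    idx = rng.choice(len(units), n_planted, replace=False)
    planted = [
        (units[i].unit_id, delta if k % 2 == 0 else -delta)
        for k, i in enumerate(idx)
    ]
    truth = dict(planted)
    design = SimDesign(planted_effects=planted, seed=seed + 3)
    calls, _ = simulate_methylome(genome, units, design)
    matrix = unit_methylation(calls, units)
    by_id = {r.unit_id: r for r in call_dmf(matrix, design.groups)}
    tested = [u for u in truth if u in by_id]
    detected = [u for u in tested if by_id[u].status != "ns"]
    sens = len(detected) / len(tested)
    agree = (
        float(
            np.mean(
                [(by_id[u].status == "hyper") == (truth[u] > 0) for u in detected]
            )
        )
        if detected
        else float("nan")
    )
    return {
        "null_rate": null_rate,
        "n_null": n_null,
        "sensitivity": sens,
        "n_planted_tested": len(tested),
        "direction_agreement": agree,
    }


def candidate_recovery(seed: int, delta: float = 0.4) -> Dict[str, float]:
    """Recovery of genes carrying planted promoter-wide methylation shifts.

    Each of 20 genes gets a +/-``delta`` shift on every CpG of its +/-2 kb
    promoter window; recovery is the fraction of genes returned as
    candidates, and direction accuracy the fraction of recovered genes whose
    hyper/hypo label matches the planted sign.
    """
    genome = simulate_genome(
        n_contigs=2, contig_len=120_000, ccgg_rate=0.012, n_genes=20, seed=seed + 10
    )
    units = _fragment_units(genome)
    lengths = genome.contig_lengths
    promoters = promoter_regions(genome.genes, lengths)
    bodies = gene_body_regions(genome.genes, lengths)

    planted = []
    truth_dir = {}
    for i, prom in enumerate(promoters):
        d = delta if i % 2 == 0 else -delta
        planted.append((prom.unit_id, d))
        truth_dir[prom.gene_id] = "hyper" if d > 0 else "hypo"

    design = SimDesign(planted_effects=planted, seed=seed + 11)
    calls, _ = simulate_methylome(genome, units + promoters, design)
    matrix = unit_methylation(calls, units)
    records = call_dmf(matrix, design.groups)
    anns = annotate_dmfs(records, matrix.units, promoters, bodies, genome.cgi_track)
    cands = {c.gene_id: c for c in select_candidates(anns)}

    recovered = [g for g in truth_dir if g in cands]
    recall = len(recovered) / len(truth_dir)
    correct = (
        float(np.mean([cands[g].direction == truth_dir[g] for g in recovered]))
        if recovered
        else float("nan")
    )
    return {
        "recall": recall,
        "direction_accuracy": correct,
        "n_genes": len(truth_dir),
    }


def cox_recovery(
    seed: int,
    beta: float = 0.7,
    n: int = 1000,
    reps: int = 200,
) -> Dict[str, float]:
    """Bias and 95% CI coverage of the Cox coefficient on exponential data."""
    estimates = []
    covered = 0
    for r in range(reps):
        tab = simulate_clinical(
            SurvivalSimDesign(
                n=n, beta_meth=beta, baseline_hazard=0.03, censor_rate=0.01,
                seed=seed + r,
            )
        )
        fit = cox_fit(
            tab["hypermethylated"].to_numpy(float),
            tab["os_time"].to_numpy(),
            tab["os_event"].to_numpy(int),
        )
        estimates.append(fit.coef[0])
        lo = fit.coef[0] - 1.96 * fit.se[0]
        hi = fit.coef[0] + 1.96 * fit.se[0]
        covered += lo <= beta <= hi
    return {
        "bias": float(np.mean(estimates) - beta),
        "ci_coverage": covered / reps,
        "n": n,
        "reps": reps,
    }
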