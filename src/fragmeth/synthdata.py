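"""Synthetic data generators for end-to-end testing of the pipeline.

Three generators cover the three stages of the analysis:

* :func:`simulate_genome` — a toy multi-contig genome with CpG dinucleotides,
  MspI sites (CCGG) and CpG islands planted at controlled rates, plus gene
  models. The background is A/T so every CG and CCGG in the sequence is one
  we planted (or part of a planted island), which makes motif counts exact
  and lets ``ccgg_rate=0`` guarantee an undigestible genome.
* :func:`simulate_methylome` — per-sample Bismark-coverage-style CpG counts
  under a beta-binomial model with planted unit-level group effects. This
  emulates the 5-case / 4-control RRBS design the pipeline was built for.
* :func:`simulate_clinical` — a right-censored survival cohort with a binary
  hypermethylation covariate of known log-hazard, plus mutation flags, for
  exercising the dichotomization, contingency and Cox stages.

Beta-binomial parameterization: per CpG per sample the methylation
probability is drawn Beta(a, b) with mean ``mu`` and dispersion ``phi``
such that Var(p) = mu (1 - mu) phi, i.e. a + b = 1/phi - 1. Depths are
Poisson(depth_mean), independent across CpGs and samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .regions import AnalysisUnit, GeneModel, assign_sites_to_units, find_cpg_sites

__all__ = [
    "SimDesign",
    "SurvivalSimDesign",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_methylome",
    "simulate_clinical",
    "simulate_control_values",
]

logger = logging.getLogger(__name__)


@dataclass
class SimDesign:
    """Design of a simulated case/control RRBS methylome.

    Defaults mirror the analysis this pipeline targets: five cases against
    four controls, conventional RRBS depth (~30x per CpG) and moderate
    beta-binomial overdispersion (phi = 0.1).
    """

    n_case: int = 5
    n_ctrl: int = 4
    baseline_mu: float = 0.5
    dispersion_phi: float = 0.1
    planted_effects: List[Tuple[str, float]] = field(default_factory=list)
    depth_mean: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("need at least one sample per group")
        if not 0.0 <= self.baseline_mu <= 1.0:
            raise ValueError("baseline_mu must lie in [0, 1]")
        if self.dispersion_phi <= 0:
            raise ValueError("dispersion_phi must be positive")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be nonnegative")

    @property
    def sample_ids(self) -> List[str]:
        return [f"case_{i+1}" for i in range(self.n_case)] + [
            f"ctrl_{i+1}" for i in range(self.n_ctrl)
        ]

    @property
    def groups(self) -> Dict[str, str]:
        return {
            s: ("case" if s.startswith("case") else "control") for s in self.sample_ids
        }


@dataclass
class SurvivalSimDesign:
    """Design of a simulated survival cohort with a binary methylation marker.

    Event times are exponential with hazard ``baseline_hazard *
    exp(beta_meth * hyper)``; censoring is an independent exponential with
    rate ``censor_rate``. ``meth_prevalence`` is the fraction of
    hypermethylated patients (default 0.35, the ballpark of a 37/105 split).
    """

    n: int = 105
    beta_meth: float = 0.0
    baseline_hazard: float = 0.03
    censor_rate: float = 0.01
    covariate_freqs: Dict[str, float] = field(default_factory=dict)
    meth_prevalence: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")
        if not 0.0 < self.meth_prevalence < 1.0:
            raise ValueError("meth_prevalence must lie in (0, 1)")
        for name, f in self.covariate_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"covariate frequency for {name} outside [0, 1]")


@dataclass
class SimulatedGenome:
    """Bundle returned by :func:`simulate_genome`."""

    contigs: Dict[str, str]
    genes: List[GeneModel]
    cgi_track: List[AnalysisUnit]

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


def _plant_motif(seq: np.ndarray, pos: int, motif: bytes) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif, dtype=np.uint8)


def simulate_genome(
    n_contigs: int = 1,
    contig_len: int = 100_000,
    cpg_rate: float = 0.04,
    ccgg_rate: float = 0.01,
    n_genes: int = 20,
    seed: int = 0,
) -> SimulatedGenome:
    """Generate a toy genome with planted CpGs, MspI sites, CGIs and genes.

    The background is random A/T; ``cpg_rate`` and ``ccgg_rate`` are the
    expected per-bp rates of planted CG dinucleotides and CCGG motifs
    (positions are drawn binomially then thinned to a 6 bp exclusion zone so
    motifs never collide). The default ``cpg_rate`` of 0.04 is deliberately
    above the genome-wide average (~0.01/bp) because this genome stands in
    for the RRBS-captured portion of a genome: size-selected MspI fragments
    are CpG-enriched by construction, and at 0.04/bp a 40-220 bp fragment
    carries the several CpGs per unit that real RRBS analysis units have. One CpG island (~60 CG repeats interleaved with
    MspI sites) is planted in each gene's promoter so that island detection
    and promoter-level effects are exercised downstream.
    """
    if n_contigs < 1 or n_genes < 0:
        raise ValueError("counts must be positive")
    if contig_len < 1000:
        raise ValueError("contig_len must be >= 1000")
    for name, r in (("cpg_rate", cpg_rate), ("ccgg_rate", ccgg_rate)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    contigs: Dict[str, str] = {}
    genes: List[GeneModel] = []
    cgis: List[AnalysisUnit] = []

    genes_per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        genes_per_contig[i] += 1

    gene_counter = 0
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        seq = rng.choice(
            np.frombuffer(b"AT", dtype=np.uint8), size=contig_len
        ).astype(np.uint8)

        occupied = np.zeros(contig_len, dtype=bool)

        def free(pos: int, width: int) -> bool:
            lo, hi = max(0, pos - 1), min(contig_len, pos + width + 1)
            return not occupied[lo:hi].any()

        def occupy(pos: int, width: int) -> None:
            occupied[pos : pos + width] = True

        # genes first: evenly spaced (promoters stay disjoint), each with a
        # CGI planted across the TSS. The island repeat is 42 bp with one
        # embedded CCGG when ccgg_rate > 0, so island-internal MspI
        # fragments (42 bp) survive the 40-220 bp size selection and every
        # promoter carries analysable fragment units.
        ng = genes_per_contig[ci]
        span = contig_len // max(ng, 1)
        if ng and span < 4400:
            raise ValueError("contig too short for the requested gene count")
        if ccgg_rate > 0:
            island = (b"CG" * 9 + b"ACCGGT" + b"CG" * 9) * 12
        else:
            island = (b"CG" * 9 + b"ATAT" + b"CG" * 9) * 12
        for gi in range(ng):
            gene_counter += 1
            gid = f"g{gene_counter:03d}"
            center = gi * span + span // 2
            jitter = (span - 4200) // 2
            tss = center + (int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0)
            length = int(rng.integers(1500, 2500))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+" and tss + length > contig_len - 10:
                strand = "-"
            if strand == "-" and tss - length < 10:
                strand = "+"
            tes = tss + length if strand == "+" else tss - length
            genes.append(GeneModel(gid, name, strand, tss, tes))
            istart = min(max(0, tss - len(island) // 2), contig_len - len(island))
            _plant_motif(seq, istart, island)
            occupy(istart, len(island))
            cgis.append(
                AnalysisUnit(
                    f"cgi:{name}:{istart}-{istart + len(island)}",
                    name,
                    istart,
                    istart + len(island),
                    "cgi",
                )
            )

        # scattered CCGG motifs (MspI sites)
        n_ccgg = rng.binomial(contig_len, ccgg_rate)
        for pos in rng.integers(0, contig_len - 4, size=n_ccgg):
            pos = int(pos)
            if free(pos, 4):
                _plant_motif(seq, pos, b"CCGG")
                occupy(pos, 4)

        # scattered CpGs
        n_cpg = rng.binomial(contig_len, cpg_rate)
        for pos in rng.integers(0, contig_len - 2, size=n_cpg):
            pos = int(pos)
            if free(pos, 2):
                _plant_motif(seq, pos, b"CG")
                occupy(pos, 2)

        contigs[name] = seq.tobytes().decode("ascii")

    return SimulatedGenome(contigs=contigs, genes=genes, cgi_track=cgis)


def _beta_binomial_fraction_counts(
    rng: np.random.Generator,
    mu: np.ndarray,
    phi: float,
    depth_mean: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (methylated, total) counts for an array of per-CpG means."""
    depth = rng.poisson(depth_mean, size=mu.shape)
    s = 1.0 / phi - 1.0
    if s <= 0:  # phi >= 1: maximal overdispersion, p in {0, 1}
        p = (rng.random(mu.shape) < mu).astype(float)
    else:
        a = np.clip(mu * s, 1e-12, None)
        b = np.clip((1.0 - mu) * s, 1e-12, None)
        p = rng.beta(a, b)
        # degenerate means stay degenerate
        p = np.where(mu <= 0.0, 0.0, np.where(mu >= 1.0, 1.0, p))
    meth = rng.binomial(depth, p)
    return meth, depth


def simulate_methylome(
    genome: SimulatedGenome,
    units: Sequence[AnalysisUnit],
    design: SimDesign,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample CpG methylation counts with planted unit effects.

    Returns ``(calls, truth)`` where ``calls`` maps sample id to a DataFrame
    with columns (contig, pos, meth, unmeth) over every covered CpG in the
    genome, and ``truth`` lists the planted units and their deltas.

    Case-group CpGs inside a planted unit have their beta mean shifted by
    that unit's delta; means pushed outside [0, 1] are clamped with a
    warning. CpGs in several planted units receive the largest-magnitude
    delta (planting disjoint units is the intended use).
    """
    unit_ids = {u.unit_id for u in units}
    for uid, _ in design.planted_effects:
        if uid not in unit_ids:
            raise KeyError(f"planted effect references unknown unit {uid!r}")

    rng = np.random.default_rng(design.seed)
    sites = {c: find_cpg_sites(seq) for c, seq in genome.contigs.items()}

    # per-contig delta vector over CpG sites
    delta_by_contig = {
        c: np.zeros(len(pos), dtype=float) for c, pos in sites.items()
    }
    if design.planted_effects:
        planted_units = {uid: d for uid, d in design.planted_effects}
        chosen = [u for u in units if u.unit_id in planted_units]
        assignment = assign_sites_to_units(sites, chosen)
        index_of = {
            c: {int(p): i for i, p in enumerate(pos)} for c, pos in sites.items()
        }
        for u in chosen:
            d = planted_units[u.unit_id]
            vec = delta_by_contig[u.contig]
            idx = index_of[u.contig]
            for p in assignment[u.unit_id]:
                i = idx[int(p)]
                if abs(d) > abs(vec[i]):
                    vec[i] = d

    clamped = 0
    calls: Dict[str, pd.DataFrame] = {}
    for sample in design.sample_ids:
        is_case = design.groups[sample] == "case"
        frames = []
        for contig, pos in sites.items():
            if pos.size == 0:
                continue
            mu = np.full(pos.size, design.baseline_mu)
            if is_case:
                mu = mu + delta_by_contig[contig]
            out_of_range = (mu < 0.0) | (mu > 1.0)
            clamped += int(out_of_range.sum())
            mu = np.clip(mu, 0.0, 1.0)
            meth, depth = _beta_binomial_fraction_counts(
                rng, mu, design.dispersion_phi, design.depth_mean
            )
            covered = depth > 0
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": pos[covered],
                        "meth": meth[covered],
                        "unmeth": (depth - meth)[covered],
                    }
                )
            )
        calls[sample] = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["contig", "pos", "meth", "unmeth"])
        )
    if clamped:
        logger.warning(
            "planted deltas pushed %d CpG means outside [0, 1]; clamped", clamped
        )

    truth = pd.DataFrame(design.planted_effects, columns=["unit_id", "delta"])
    return calls, truth


def simulate_clinical(design: SurvivalSimDesign) -> pd.DataFrame:
    """Simulate a clinical table with survival endpoints and mutation flags.

    Columns: patient_id, hypermethylated (0/1), methylation_value (continuous,
    consistent with the binary status), one 0/1 column per covariate in
    ``covariate_freqs``, os_time / os_event and lfs_time / lfs_event.
    Both endpoints share the same hazard model in this generator.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n
    hyper = (rng.random(n) < design.meth_prevalence).astype(int)
    # continuous marker: non-hyper values ~ |N(0.2, 0.1)|, hyper shifted up
    value = np.abs(rng.normal(0.2, 0.1, size=n)) + hyper * rng.uniform(0.5, 1.5, size=n)

    hazard = design.baseline_hazard * np.exp(design.beta_meth * hyper)
    event_time = rng.exponential(1.0 / hazard)
    if design.censor_rate > 0:
        censor_time = rng.exponential(1.0 / design.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)

    def endpoint(et: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        t = np.minimum(et, censor_time)
        e = (et <= censor_time).astype(int)
        return t, e

    os_t, os_e = endpoint(event_time)
    # LFS: an earlier correlated event under the same hazard
    lfs_raw = np.minimum(event_time, rng.exponential(1.0 / hazard))
    lfs_t, lfs_e = endpoint(lfs_raw)

    table = pd.DataFrame(
        {
            "patient_id": [f"p{i + 1:03d}" for i in range(n)],
            "hypermethylated": hyper,
            "methylation_value": value,
            "os_time": os_t,
            "os_event": os_e,
            "lfs_time": lfs_t,
            "lfs_event": lfs_e,
        }
    )
    for name, freq in design.covariate_freqs.items():
        table[name] = (rng.random(n) < freq).astype(int)
    return table


def simulate_control_values(
    n: int,
    mean: float = 0.2,
    sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Control-group marker values for exercising the mean + 2 SD cutoff."""
    if n < 2:
        raise ValueError("need at least two control values")
    rng = np.random.default_rng(seed)
    return np.abs(rng.normal(mean, sd, size=n))
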