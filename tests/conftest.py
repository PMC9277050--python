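import numpy as np
import pytest

from fragmeth.diffmeth import call_dmf, unit_methylation
from fragmeth.digest import msp_fragments
from fragmeth.regions import AnalysisUnit
from fragmeth.synthdata import SimDesign, simulate_genome, simulate_methylome


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-contig genome with genes and planted CpG islands."""
    return simulate_genome(
        n_contigs=2, contig_len=60_000, cpg_rate=0.04, ccgg_rate=0.012,
        n_genes=10, seed=11,
    )


@pytest.fixture(scope="session")
def toy_fragments(toy_genome):
    return msp_fragments(toy_genome.contigs)


@pytest.fixture(scope="session")
def toy_fragment_units(toy_fragments):
    return [
        AnalysisUnit(f.fragment_id, f.contig, f.start, f.end, "fragment")
        for f in toy_fragments
    ]


@pytest.fixture(scope="session")
def planted_run(toy_genome, toy_fragment_units):
    """A full simulated case/control run with +/-0.4 effects planted on
    80 fragments, aggregated and DMF-called under package defaults."""
    units = toy_fragment_units
    rng = np.random.default_rng(5)
    idx = rng.choice(len(units), 80, replace=False)
    planted = [
        (units[i].unit_id, 0.4 if k % 2 == 0 else -0.4) for k, i in enumerate(idx)
    ]
    design = SimDesign(planted_effects=planted, seed=11)
    calls, truth = simulate_methylome(toy_genome, units, design)
    matrix = unit_methylation(calls, units)
    records = call_dmf(matrix, design.groups)
    return {
        "design": design,
        "calls": calls,
        "truth": truth,
        "matrix": matrix,
        "records": records,
        "planted": dict(planted),
    }
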