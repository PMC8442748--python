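from dataclasses import dataclass

import numpy as np
import pytest

from bsamap import pipeline, simdata, snp_index


def small_layout(causal: bool = True) -> simdata.GenomeLayout:
    """Three 2 Mb chromosomes, 30 SNPs each, causal mid-chromosome 2."""
    rng = np.random.default_rng(7)
    chroms = tuple((f"c{i}", 2_000_000) for i in range(1, 4))
    positions = {
        name: np.sort(rng.choice(np.arange(1, length + 1), 30, replace=False))
        for name, length in chroms
    }
    cpos = positions["c2"]
    causal_locus = ("c2", int(cpos[len(cpos) // 2])) if causal else None
    return simdata.GenomeLayout(chroms, positions, causal_locus)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated experiment shared by fast unit tests."""
    layout = small_layout()
    config = simdata.SimConfig(n_f2=150, recomb_rate=0.1, seed=11)
    return simdata.simulate_case(config, layout=layout, seed=11)


@dataclass
class SeedOutcome:
    fitted_at_causal: float
    causal_in_top_region: bool
    stat_concordant: bool


@pytest.fixture(scope="session")
def multi_seed_outcomes():
    """Fifty default-condition simulations (bulks of 30, 34x depth, 1% base
    error), each filtered and scanned; the backbone of the stochastic
    parameter-recovery checks."""
    outcomes = []
    for seed in range(1, 51):
        res = simdata.simulate_case(simdata.SimConfig(), seed=seed)
        chrom, pos = res.layout.causal_locus
        scan = pipeline.run_scan(res.sites, threshold="fixed:0.56")
        fitted = pipeline.fitted_at(scan.tracks, chrom, pos)
        top = snp_index.top_peak_region(scan.regions)
        contained = top is not None and top.chrom == chrom and top.start <= pos <= top.end
        raw_delta = pipeline.run_scan(res.sites, apply_filter=False)
        raw_ed = pipeline.run_scan(res.sites, stat="ed", apply_filter=False)
        concordant = snp_index.top_peak_chrom(raw_delta.tracks) == snp_index.top_peak_chrom(
            raw_ed.tracks
        )
        outcomes.append(SeedOutcome(fitted, contained, concordant))
    return outcomes
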