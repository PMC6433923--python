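import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from rnaedit import pipeline as pl
from rnaedit import simulate as sim


def make_pileup(rows):
    """Build a pileup frame from (chrom, pos, ref, counts-dict) tuples."""
    out = []
    for chrom, pos, ref, counts in rows:
        base = {c: 0 for c in pl.COUNT_COLUMNS}
        base.update(counts)
        out.append({"chrom": chrom, "pos": pos, "ref": ref, **base})
    return pd.DataFrame(out, columns=["chrom", "pos", "ref", *pl.COUNT_COLUMNS])


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort shared across tests (read-only)."""
    cfg = sim.SimConfig(n_individuals=8, n_sites=1200, seed=11)
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_sim_calls(small_sim):
    """Per-individual matched calls on the small cohort."""
    by = {}
    for ind in small_sim.truth.individuals:
        cands, _ = pl.run_matched_individual(
            ind,
            small_sim.counts[(ind, "normal", "rna")],
            small_sim.counts[(ind, "normal", "dna")],
            small_sim.counts[(ind, "tumor", "rna")],
            small_sim.counts[(ind, "tumor", "dna")],
            small_sim.variants[(ind, "normal")],
            small_sim.variants[(ind, "tumor")],
        )
        by[ind] = cands
    return by
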