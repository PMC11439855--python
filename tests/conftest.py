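import numpy as np
import pytest
from hypothesis import settings

from palemapper import simulate

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_cross():
    """One desk-scale cross simulated at the default study conditions."""
    cfg = simulate.CrossSimConfig(seed=7)
    cohort = simulate.simulate_f2_population(cfg)
    records = simulate.pool_and_sequence(cohort, cfg)
    return cfg, cohort, records


@pytest.fixture(scope="session")
def r298k_fixture():
    """Synthetic gene with an AGA (Arg) codon at index 298 and one intron,
    so genomic and spliced-CDS coordinates differ."""
    model, cds, genome_seqs = simulate.make_gene_fixture(
        400, substitutions=[(298, "AGA")], intron_layout=[(100, 500)]
    )
    return model, cds, genome_seqs


@pytest.fixture()
def noiseless_season():
    cfg = simulate.LoadCellSimConfig(n_days=5, noise_sd=0.0, seed=3)
    return cfg, simulate.simulate_loadcell_season(cfg)


@pytest.fixture()
def cohort_131_434():
    """A cohort with exactly the observed phenotype-class split 131:434."""
    n_mut, n_wt = 131, 434
    classes = np.array(
        [simulate.MUTANT_LIKE] * n_mut + [simulate.WT_LIKE] * n_wt
    )
    n = n_mut + n_wt
    return simulate.F2Cohort(
        marker_chrom=np.array(["chr1H"]),
        marker_pos=np.array([1]),
        genotypes=np.zeros((n, 1), dtype=np.int8),
        true_class=classes,
        phenotype_class=classes,
        causal_index=None,
    )
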