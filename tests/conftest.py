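import numpy as np
import pytest

from mksel import io_formats as io
from mksel.synthetic_data import (
    SimulationTruth,
    simulate_mk_counts,
    simulate_two_species_vcf,
    _write_vcf,
)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The two-species VCF fixture, written to disk and read back through
    the real I/O layer (files -> pysam -> VariantRecords)."""
    td = tmp_path_factory.mktemp("fixture")
    fx = simulate_two_species_vcf(seed=3, out_dir=td)
    fx["dir"] = td
    fx["focal_records"] = io.read_vcf(td / "focal.vcf")
    fx["outgroup_records"] = io.read_vcf(td / "outgroup.vcf")
    return fx


@pytest.fixture(scope="session")
def recovery_sim():
    """The 500-gene PRF recovery simulation at the study conditions
    (n = 20, z = 2.5, d = 1, seed 1)."""
    truth = SimulationTruth.default(500, frac_positive=0.12, seed=1)
    tables, truth_df = simulate_mk_counts(truth, seed=1)
    return truth, tables, truth_df


@pytest.fixture(scope="session")
def eb_estimates(recovery_sim):
    from mksel.selection_inference import ModelConfig, fit_hierarchical_mk

    _, tables, _ = recovery_sim
    return fit_hierarchical_mk(
        tables, ModelConfig(n=20, estimator="empirical_bayes")
    )
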