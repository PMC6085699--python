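import numpy as np
import pytest

from clonemate import Platform, Probe, ProbeProfile, SimulationConfig, simulate_cohort
from clonemate.simulate import recover_labels


def make_profile(values, platform=Platform.COPY_NUMBER, sample_id="S1", chrom="1"):
    """Probe profile on a simple one-chromosome grid."""
    probes = [Probe(f"p{i}", chrom, (i + 1) * 1000) for i in range(len(values))]
    return ProbeProfile(sample_id, platform, probes, np.asarray(values, float))


@pytest.fixture(scope="session")
def null_calibration():
    """Rejection rates of the permutation tests on zero-signal cohorts.

    500 seeded cohorts of 20 patients with 500 copy-number probes and no
    clonal patients; every rejection is a false positive. Shared across
    tests because the simulation loop dominates runtime.
    """
    methods = ("distance", "shared_segments", "shared_mutations", "si")
    rates = {m: [] for m in methods}
    for s in range(500):
        data = simulate_cohort(
            SimulationConfig(seed=100_000 + s, clonal_fraction=0.0,
                             n_patients=20, n_probes=500)
        )
        for m in methods:
            rates[m].append(1.0 - recover_labels(data, m)["specificity"])
    return {m: np.asarray(v) for m, v in rates.items()}


def mc_band(rates: np.ndarray, target: float = 0.05, k: float = 3.0):
    """Monte-Carlo acceptance band: target +/- k standard errors.

    The standard error is the between-cohort one, because the decisions
    within a cohort share its artificial-pair null and are correlated.
    """
    se = rates.std(ddof=1) / np.sqrt(len(rates))
    return target - k * se, target + k * se
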