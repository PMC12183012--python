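import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exomy import simcov
from exomy.refmodel import TargetInterval, default_target_map

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def targets():
    return default_target_map()


@pytest.fixture(scope="session")
def params():
    return simcov.DepthParams(seed=7)


@pytest.fixture(scope="session")
def batch(targets, params):
    rng = np.random.default_rng(7)
    return simcov.CaptureBatch.draw(targets, params, rng)


@pytest.fixture(scope="session")
def reference(targets, params, batch):
    rng = np.random.default_rng(8)
    return simcov.simulate_reference_cohort(20, params, targets, batch, rng)


@pytest.fixture(scope="session")
def mini_targets():
    """A handful of targets for Monte-Carlo-heavy tests."""
    return [
        TargetInterval("chr1", 1000, 1300, "a1", None, None, 2, None),
        TargetInterval("chr1", 2000, 2300, "a2", None, None, 2, None),
        TargetInterval("chr1", 3000, 3300, "a3", None, None, 2, None),
        TargetInterval("chrX", 5_000_000, 5_000_300, "x1", None, None, 1, None),
        TargetInterval("chrY", 2_655_081, 2_655_782, "sry", "SRY", None, 1, None),
        TargetInterval("chrY", 14_813_160, 14_813_460, "usp9y", "USP9Y",
                       None, 1, "AZFa"),
        TargetInterval("chrY", 25_275_502, 25_275_802, "daz1", "DAZ1",
                       "DAZ", 4, "AZFc"),
        TargetInterval("chrY", 26_909_216, 26_909_516, "daz3", "DAZ3",
                       "DAZ", 4, "AZFc"),
    ]


def noiseless_profile(spec, targets):
    """Expectation-valued dosage profile for a genotype spec (no noise)."""
    from exomy.depthcnv import DosageProfile
    loci = simcov.build_gene_loci(targets)
    dosages = {}
    for t in targets:
        copies = spec.target_copies(t, loci)
        dosages[t.target_id] = float(copies)
    return DosageProfile(sample_id="noiseless", targets=list(targets),
                         dosages=dosages)
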