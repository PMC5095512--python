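import numpy as np
import pytest

import unseenest as u


@pytest.fixture(scope="session")
def neutral_cohort():
    """Synonymous-like study condition: 1/x spectrum, T=50k variants, k=2000."""
    scen = u.neutral_like_scenario(T=50_000, k=2_000, seed=0)
    h_true, cohort = u.simulate_scenario(scen)
    return h_true, cohort


@pytest.fixture(scope="session")
def lof_cohort():
    """Deleterious-like condition: Beta(0.5, 5000), T=50k variants, k=2000."""
    scen = u.lof_like_scenario(T=50_000, k=2_000, seed=1)
    h_true, cohort = u.simulate_scenario(scen)
    return h_true, cohort


@pytest.fixture(scope="session")
def annotated_vcf(tmp_path_factory):
    """Two-population annotated fixture VCF plus its generating cohort."""
    scen = u.SimScenario(
        model="beta", T=600, k=200, seed=3, beta_a=0.5, beta_b=50.0,
        populations={"AFR": 0.3, "EUR": 0.7},
    )
    h_true, cohort = u.simulate_scenario(scen)
    path = tmp_path_factory.mktemp("vcf") / "fixture.vcf"
    u.write_fixture_vcf(cohort, scen, path)
    return path, scen, cohort


def random_histogram(rng, n_points=12, t_scale=1000.0):
    """A random valid histogram for property-style checks."""
    x = np.sort(rng.uniform(1e-5, 1.0, size=n_points))
    x = np.unique(x)
    mass = rng.uniform(0.0, t_scale, size=len(x))
    return u.FrequencyHistogram(u.FrequencyGrid(x), mass)
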