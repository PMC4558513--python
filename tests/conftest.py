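import pytest

from mlpa_ddr import (
    GeneratorConfig,
    compute_fi_table,
    default_panel,
    fit,
    resolve_profile,
    select_probes,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    """Default-separation synthetic training cohort (n=30/group, seed 1),
    already pushed through quantification and probe selection."""
    config = GeneratorConfig(n_per_group=30, seed=1)
    measurements, metadata = simulate_cohort(config)
    fi = compute_fi_table(measurements, panel)
    selection = select_probes(fi, metadata, panel)
    profiles, not_evaluable = resolve_profile(fi, selection)
    assert not not_evaluable
    return {
        "config": config,
        "measurements": measurements,
        "metadata": metadata,
        "fi": fi,
        "selection": selection,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def trained_model(cohort, panel):
    return fit(cohort["profiles"], cohort["metadata"], panel)
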