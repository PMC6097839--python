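import hypothesis
import pytest

from riboteq import AgingScenario, make_gene_models, make_spikein_reference
from riboteq.synthetic import simulate_experiment

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down aging scenario for fast unit tests."""
    return AgingScenario(
        n_genes=300,
        n_rpg=20,
        n_affected=150,
        mean_reads_per_gene=1500.0,
        n_spikes=24,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_scenario):
    models = make_gene_models(small_scenario)
    spikes = make_spikein_reference(small_scenario.n_spikes, small_scenario.seed)
    cm, truth = simulate_experiment(models, spikes, small_scenario)
    return models, spikes, cm, truth
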