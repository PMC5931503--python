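import numpy as np
import pytest

from isodiet.defaults import DEFAULT_SOURCES, DEFAULT_TEF
from isodiet.mixing_model import DietPosterior, MixingModelSpec, sample_posterior
from isodiet.synthetic_data import (
    SimulationConfig,
    simulate_consumers,
    simulate_diet_proportions,
    simulate_remains,
)
from isodiet.types import ConsumerObservation


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study: truth, consumer samples, remains records."""
    cfg = SimulationConfig(n_territories=8, occupancy=0.6, seed=42)
    truth = simulate_diet_proportions(cfg)
    samples = simulate_consumers(truth, cfg)
    remains = simulate_remains(truth, cfg)
    return cfg, truth, samples, remains


@pytest.fixture(scope="session")
def quick_fit():
    """A short but converged fit of three synthetic nest-years."""
    cfg = SimulationConfig(n_territories=3, years=(2012,), occupancy=1.0, seed=7)
    truth = simulate_diet_proportions(cfg)
    samples = simulate_consumers(truth, cfg)
    from isodiet.isotope_prep import average_siblings

    obs = average_siblings(samples)
    spec = MixingModelSpec(
        sources=DEFAULT_SOURCES,
        tef=DEFAULT_TEF,
        consumers=tuple(obs),
        n_chains=4,
        n_iter=2000,
        n_burnin=500,
        seed=7,
    )
    return truth, spec, sample_posterior(spec)


def make_posterior(draws: np.ndarray, names=("a", "b")) -> DietPosterior:
    """Build a DietPosterior directly from a (n_obs, chains, kept, K) array."""
    draws = np.asarray(draws, dtype=float)
    consumers = tuple(
        ConsumerObservation(f"N{i}", 2012, -22.0, 10.0) for i in range(draws.shape[0])
    )
    resid = np.full(draws.shape[:3] + (2,), 0.1)
    return DietPosterior(
        consumers=consumers, source_names=tuple(names), proportions=draws, residual_sd=resid
    )
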