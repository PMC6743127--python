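import numpy as np
import pytest

from dpi_usability.bayes import PosteriorDraws
from dpi_usability.scoring import default_scheme, validate_scheme
from dpi_usability.simulate import SimulationParams, generate_cohort, paper_design

TRUE_EFFECTS = (0.0, 2.0, 10.0, -4.0, 4.0, 6.0, 8.0)  # canonical device order


@pytest.fixture(scope="session")
def scheme():
    return validate_scheme(default_scheme())


@pytest.fixture(scope="session")
def paper_cohort():
    """One simulated cohort on the published design (FE truth, tau = 5)."""
    params = SimulationParams(
        true_effects=TRUE_EFFECTS, respondent_sd=5.0, residual_sd=5.0, seed=2024
    )
    records, truth = generate_cohort(paper_design(), params)
    return records, truth


@pytest.fixture(scope="session")
def experienced_records(paper_cohort):
    records, _ = paper_cohort
    return [r for r in records if r.stratum == "experienced"]


def make_draws(
    d,
    mu=None,
    tau=None,
    chain=None,
    devices=("Breezhaler", "Diskus"),
    reference="Breezhaler",
    **kwargs,
):
    """Hand-built PosteriorDraws for oracle tests on stored matrices."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if mu is None:
        mu = np.zeros((n, 1))
    if tau is None:
        tau = np.ones(n)
    if chain is None:
        chain = np.zeros(n, dtype=int)
    return PosteriorDraws(
        model_type="FE",
        devices=tuple(devices),
        reference=reference,
        respondent_ids=tuple(f"R{i}" for i in range(np.asarray(mu).shape[1])),
        d=d,
        mu=np.asarray(mu, dtype=float),
        tau=np.asarray(tau, dtype=float),
        chain=np.asarray(chain),
        **kwargs,
    )
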