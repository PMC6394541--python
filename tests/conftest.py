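"""Shared fixtures: simulated cohorts and fitted models reused across tests.

The expensive hierarchical fits are session-scoped so each is run once.
"""

import warnings

import pytest

import dtmilk


@pytest.fixture(scope="session")
def standard_cohort():
    """20 pairs from the default truth (reported covariate-model values,
    between-subject log-sd 0.2, small combined noise)."""
    truth = dtmilk.SimulationTruth()
    design = dtmilk.CohortDesign(n_pairs=20)
    return dtmilk.simulate_cohort(truth, design, seed=1)


@pytest.fixture(scope="session")
def fitted_full(standard_cohort):
    """Full covariate / combined-error fit at the desk-scale protocol."""
    model = dtmilk.HierarchicalDtmModel(
        covariate_model="full",
        error_model="combined",
        n_chains=3,
        n_draws=1000,
        n_warmup=1500,
        thin=5,
        random_state=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(standard_cohort.pairs)
    return model


@pytest.fixture(scope="session")
def fitted_additive(standard_cohort):
    """Deliberately misspecified residual model (additive only) on the same
    data, for model-comparison checks."""
    model = dtmilk.HierarchicalDtmModel(
        covariate_model="full",
        error_model="additive",
        n_chains=2,
        n_draws=500,
        n_warmup=1200,
        thin=3,
        random_state=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(standard_cohort.pairs)
    return model


@pytest.fixture(scope="session")
def fitted_full_small(standard_cohort):
    """Same generating model fitted at the settings of ``fitted_additive``
    so the two are comparable by WAIC/LOO."""
    model = dtmilk.HierarchicalDtmModel(
        covariate_model="full",
        error_model="combined",
        n_chains=2,
        n_draws=500,
        n_warmup=1200,
        thin=3,
        random_state=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(standard_cohort.pairs)
    return model


@pytest.fixture(scope="session")
def perfect_cohort():
    """10 perfect exclusively-breastfeeding pairs (true Rs = 0)."""
    truth = dtmilk.SimulationTruth(rs_per_pair=0.0)
    design = dtmilk.CohortDesign(n_pairs=10)
    return dtmilk.simulate_cohort(truth, design, seed=11)


@pytest.fixture(scope="session")
def perfect_fit(perfect_cohort):
    model = dtmilk.HierarchicalDtmModel(
        n_chains=3, n_draws=800, n_warmup=1200, thin=4, random_state=11
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(perfect_cohort.pairs)
    return model
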