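import numpy as np
import pytest

import normbandit as nb


@pytest.fixture(scope="session")
def design_1a():
    return nb.build_design("1a")


@pytest.fixture(scope="session")
def design_3a():
    return nb.build_design("3a")


@pytest.fixture(scope="session")
def range_model():
    return nb.ModelSpec("RANGE")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def simulated_range_subject(design_1a, range_model):
    """One RANGE agent with known parameters, all three phases."""
    params = nb.AgentParameters(alpha_c=0.3, alpha_u=0.15, beta=5.0)
    return nb.simulate_subject(
        range_model, params, design_1a, seed=2024, subject_id="s0"
    )


def oracle_learning_negloglik(params, model, records, design):
    """Independent brute-force replay of the learning-phase likelihood,
    built trial by trial from the public single-step operations (kept
    separate from the compiled path used by the fitting code)."""
    state = nb.ValueState.initialize(design, model)
    total = 0.0
    for rec in sorted(records, key=lambda r: r.trial_index):
        raw = [o if o is not None else np.nan for o in rec.outcomes]
        resolved = nb.resolve_feedback(state, raw, rec.observed_mask, rec.option_ids)
        ci = rec.chosen_index
        if not rec.forced:
            q = [state.q[(rec.context_id, o)] for o in rec.option_ids]
            total -= nb.log_softmax_probability(q, params.beta, ci, rec.available)
        u = nb.subjective_outcomes(model, resolved, ci, params)
        nb.update_values(state, rec.context_id, rec.option_ids, u, ci, params)
    return total
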