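import pytest

from chelapower import get_preset, simulate_progress


@pytest.fixture(scope="session")
def fig2b_curve():
    """Regenerated assay (1 mM ATP, 2 mM PEP): long steady state."""
    p = get_preset("fig2b")
    return simulate_progress(p.params, p.conditions, p.t_end, p.n_out)


@pytest.fixture(scope="session")
def fig2a_noregen_curve():
    """0.5 mM ATP, no regeneration: rise and fall of MgD."""
    p = get_preset("fig2a-noregen")
    return simulate_progress(p.params, p.conditions, p.t_end, p.n_out)
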