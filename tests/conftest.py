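import numpy as np
import pytest

from ptsdconn.simulate import SimulationConfig, simulate_cohort_connectomes


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded default cohort (40 nodes, 36+36 subjects) shared by tests."""
    cfg = SimulationConfig(seed=3)
    conns, cohort, planted = simulate_cohort_connectomes(cfg)
    return cfg, conns, cohort, planted


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def baseline_patient_edges(conns, cohort):
    """Edge matrix (patients x edges) and residual change, baseline session."""
    base = {c.subject_id: c for c in conns if c.session == "baseline"}
    pats = cohort[cohort["group"] == "patient"]
    x = np.vstack([base[s].edge_vector() for s in pats["subject_id"]])
    y = pats["residual_change"].to_numpy(dtype=float)
    return x, y
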