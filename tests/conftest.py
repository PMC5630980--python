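import pytest

from lncmir import simulate

ALL_VIOLATIONS = (
    "none", "none", "none", "none",
    "mismatch_budget", "cut_site", "multiloop", "loop_overlap",
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study shared across read-only tests."""
    cfg = simulate.SimConfig(
        n_genes=40,
        n_planted_hairpins=8,
        planted_violations=ALL_VIOLATIONS,
        seed=7,
    )
    return simulate.simulate_study(cfg)
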