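import pytest

import hanlon as h


@pytest.fixture
def pilot_panel() -> h.RaterPanel:
    """12 identical rater sheets carrying the pilot-test consensus means."""
    return h.pilot_consensus_panel(12)


@pytest.fixture
def pearl_toy_scores() -> dict[str, h.ComponentScores]:
    """Three programs, the middle one failing a single PEARL criterion."""
    def cs(pearl: h.PearlFlags) -> h.ComponentScores:
        return h.ComponentScores(size_a=5, seriousness=10, effectiveness=5,
                                 pearl=pearl)
    return {
        "P1": cs(h.PearlFlags(1, 1, 1, 1, 1)),
        "P2": cs(h.PearlFlags(0, 1, 1, 1, 1)),
        "P3": cs(h.PearlFlags(1, 1, 1, 1, 1)),
    }


def random_scenario(rng, *, n_programs=None, n_raters=None,
                    noise_sd=1.0) -> h.PanelScenario:
    """A random but always-valid scenario for property tests."""
    n_programs = n_programs or int(rng.integers(2, 8))
    n_raters = n_raters or int(rng.integers(2, 8))
    true = {}
    for i in range(n_programs):
        true[f"X{i}"] = h.ComponentScores(
            size_a=float(rng.uniform(0, 10)),
            seriousness=float(rng.uniform(0, 20)),
            effectiveness=float(rng.uniform(0, 10)),
            inequity_e=float(rng.uniform(0, 5)),
            positioning_f=float(rng.uniform(2 / 3, 1.5)),
        )
    return h.PanelScenario(true_components=true, n_raters=n_raters,
                           noise_sd=noise_sd,
                           seed=int(rng.integers(0, 2**31 - 1)))
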