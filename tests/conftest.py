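"""Shared fixtures: one small simulated scenario reused across test modules."""

import pandas as pd
import pytest

import boxnet as bn


SMALL = bn.ScenarioConfig(
    n_individuals=40,
    n_groups=4,
    n_sections=2,
    boxes_per_section=10,
    seed=123,
)


@pytest.fixture(scope="session")
def small_config() -> bn.ScenarioConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_scenario() -> bn.Scenario:
    return bn.simulate_scenario(SMALL)


@pytest.fixture(scope="session")
def small_stacks(small_scenario):
    return bn.make_stacks(
        small_scenario.events, small_scenario.schedule, small_scenario.roster
    )


@pytest.fixture(scope="session")
def small_response_table(small_scenario, small_stacks):
    from boxnet import metrics as met
    from boxnet import models as mod

    sc = small_scenario
    full, surv = small_stacks
    attrs = bn.loss_attributes(full[sc.schedule.last_pre_index], sc.roster.missing)
    delta = met.delta_from_baseline(surv)
    table = mod.build_response_table(delta, attrs)
    return table[table["individual_id"].isin(surv.common_nodes)].reset_index(drop=True)


def make_events(rows) -> pd.DataFrame:
    """Event frame from (individual, box, section, entry, exit) tuples."""
    return pd.DataFrame(
        rows, columns=["individual_id", "box_id", "section", "entry", "exit"]
    )
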