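import numpy as np
import pytest

from isoquantal.data import DoseResponseDataset, QuantalDoseGroup
from isoquantal.simulate import DrugTruth, SimulationScenario, simulate_single_drug


@pytest.fixture
def symmetric_dataset() -> DoseResponseDataset:
    """Log-symmetric design with symmetric responses: ED50 = 10 exactly."""
    return DoseResponseDataset(
        "SYM",
        (QuantalDoseGroup(1.0, 8, 0),
         QuantalDoseGroup(10.0, 8, 4),
         QuantalDoseGroup(100.0, 8, 8)),
    )


@pytest.fixture
def fixed_dataset() -> DoseResponseDataset:
    """Frozen synthetic dataset: true log10 ED50 = 1.2, slope = 3, five
    doses of 8 animals, seed 42."""
    scenario = SimulationScenario(
        drugs=(DrugTruth("D", 1.2, 3.0),), seed=42)
    return simulate_single_drug(scenario, "D")


@pytest.fixture
def study_scenario() -> SimulationScenario:
    """Canonical three-drug simulation scenario: parallel lines (slope 3
    probits per log10 dose) and realistic anticonvulsant potencies."""
    return SimulationScenario(
        drugs=(DrugTruth("A", np.log10(8.0), 3.0),
               DrugTruth("B", np.log10(25.0), 3.0),
               DrugTruth("C", np.log10(60.0), 3.0)),
        true_interaction_index=1.0, seed=0)
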