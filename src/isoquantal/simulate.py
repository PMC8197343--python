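"""Synthetic quantal dose-response experiments with known ground truth.

The generator emulates the design of a mouse MES anticonvulsant screen:
groups of 8 animals per dose, a 5-step geometric dose ladder bracketing the
ED50 (spanning the 10-90% response band so that mid-curve doses exist for
the informative-animal rule), and binomially sampled protection counts from
a probit-linear curve on log10 dose,

    n_responders ~ Binomial(group_size, Phi(slope * (log10 d - log10 ED50))).

Mixtures are simulated as single probit agents whose true ED50 is a chosen
multiple (the true interaction index) of the Loewe-additive prediction from
the component truths, and whose slope is the fraction-weighted mean of the
component slopes; an index of 1 makes the mixture exactly additive.

Randomness: one numpy Generator stream per dataset, derived from the
scenario's master seed and a CRC32 of the dataset label, so that outputs
are reproducible run-to-run and independent across datasets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .additivity import MixtureSpec, additive_ed50
from .data import DoseResponseDataset, QuantalDoseGroup, SummaryEffectRecord
from .interaction import InteractionResult, analyze_combination
from .probit import NonIdentifiableError, fit_log_probit

__all__ = ["DrugTruth", "SimulationScenario", "default_dose_ladder",
           "simulate_single_drug", "simulate_mixture",
           "simulate_combination_trial", "TrialOutcome"]

DEFAULT_GROUP_SIZE = 8
DEFAULT_N_DOSES = 5
DEFAULT_SPAN = (0.10, 0.90)


@dataclass(frozen=True)
class DrugTruth:
    """True probit-line parameters for one simulated drug."""

    label: str
    log10_ed50: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("true slope must be positive")

    @property
    def ed50(self) -> float:
        return 10.0 ** self.log10_ed50

    def protection_probability(self, dose) -> np.ndarray:
        z = self.slope * (np.log10(np.asarray(dose, dtype=float))
                          - self.log10_ed50)
        return stats.norm.cdf(z)


@dataclass(frozen=True)
class SimulationScenario:
    """Design of a simulated fixed-ratio combination experiment.

    ``true_interaction_index`` scales the mixture's true ED50 relative to
    the additive prediction from the component truths (1.0 = additive,
    < 1 synergy, > 1 antagonism).  ``dose_ladders`` may pin explicit ladders
    per subject label; by default each subject gets a geometric ladder
    spanning its own 10-90% response band.
    """

    drugs: tuple[DrugTruth, ...]
    fractions: tuple[float, ...] | None = None
    true_interaction_index: float = 1.0
    group_size: int = DEFAULT_GROUP_SIZE
    n_doses: int = DEFAULT_N_DOSES
    response_span: tuple[float, float] = DEFAULT_SPAN
    dose_ladders: Mapping[str, Sequence[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.true_interaction_index <= 0:
            raise ValueError("true_interaction_index must be positive")
        if self.fractions is None:
            k = len(self.drugs)
            object.__setattr__(self, "fractions", tuple(1.0 / k for _ in self.drugs))
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    def drug(self, label: str) -> DrugTruth:
        for d in self.drugs:
            if d.label == label:
                return d
        raise KeyError(label)

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=seed)

    @property
    def mixture_label(self) -> str:
        return " + ".join(d.label for d in self.drugs)

    def mixture_truth(self) -> DrugTruth:
        """The mixture's own true probit line under the injected index."""
        ed50_add_true = sum(f * d.ed50 for f, d in zip(self.fractions, self.drugs))
        slope = sum(f * d.slope for f, d in zip(self.fractions, self.drugs))
        ed50_mix = self.true_interaction_index * ed50_add_true
        return DrugTruth(self.mixture_label, float(np.log10(ed50_mix)), slope)


def default_dose_ladder(truth: DrugTruth, n_doses: int = DEFAULT_N_DOSES,
                        span: tuple[float, float] = DEFAULT_SPAN) -> np.ndarray:
    """Geometric dose ladder whose ends sit at the given response span."""
    lo, hi = (truth.log10_ed50 + stats.norm.ppf(q) / truth.slope for q in span)
    return np.logspace(lo, hi, n_doses)


def _stream(scenario: SimulationScenario, label: str) -> np.random.Generator:
    # per-dataset child stream: master seed + stable label hash
    return np.random.default_rng(
        np.random.SeedSequence([scenario.seed & 0x7FFFFFFF,
                                zlib.crc32(label.encode("utf-8"))])
    )


def _sample_dataset(scenario: SimulationScenario, truth: DrugTruth,
                    metadata: Mapping[str, str]) -> DoseResponseDataset:
    doses = np.asarray(
        scenario.dose_ladders.get(truth.label, default_dose_ladder(
            truth, scenario.n_doses, scenario.response_span)), dtype=float)
    rng = _stream(scenario, truth.label)
    probs = truth.protection_probability(doses)
    counts = rng.binomial(scenario.group_size, probs)
    groups = tuple(
        QuantalDoseGroup(float(d), scenario.group_size, int(k))
        for d, k in zip(doses, counts)
    )
    return DoseResponseDataset(truth.label, groups, metadata=dict(metadata))


def simulate_single_drug(scenario: SimulationScenario,
                         drug: str | DrugTruth) -> DoseResponseDataset:
    """Binomial protection counts for one drug's dose ladder."""
    truth = scenario.drug(drug) if isinstance(drug, str) else drug
    meta = {"true_log10_ed50": repr(truth.log10_ed50),
            "true_slope": repr(truth.slope)}
    return _sample_dataset(scenario, truth, meta)


def simulate_mixture(scenario: SimulationScenario) -> DoseResponseDataset:
    """Total-dose ladder for the fixed-ratio mixture under the injected
    true interaction index."""
    truth = scenario.mixture_truth()
    meta = {"true_log10_ed50": repr(truth.log10_ed50),
            "true_slope": repr(truth.slope),
            "true_interaction_index": repr(scenario.true_interaction_index)}
    return _sample_dataset(scenario, truth, meta)


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated combination experiment pushed through the pipeline."""

    result: InteractionResult
    true_interaction_index: float
    true_ed50_add: float
    true_ed50_mixture: float
    single_fits: tuple
    mixture_fit: object


def simulate_combination_trial(scenario: SimulationScenario) -> TrialOutcome:
    """Full in-silico replicate: simulate + fit singles, build the additive
    prediction, simulate + fit the mixture, classify the interaction.

    Raises :class:`~isoquantal.probit.NonIdentifiableError` if any sampled
    dataset cannot support a probit fit (all-extreme responses); callers
    running replicate studies should count such replicates separately.
    """
    single_fits = tuple(
        fit_log_probit(simulate_single_drug(scenario, d)) for d in scenario.drugs
    )
    spec = MixtureSpec(
        tuple((f.dataset.subject_label, f.to_summary_record())
              for f in single_fits),
        scenario.fractions, label=scenario.mixture_label)
    mix_fit = fit_log_probit(simulate_mixture(scenario))
    result = analyze_combination(mix_fit.to_summary_record(), spec,
                                 label=scenario.mixture_label)
    truth = scenario.mixture_truth()
    ed50_add_true = sum(f * d.ed50 for f, d in zip(scenario.fractions,
                                                   scenario.drugs))
    return TrialOutcome(result=result,
                        true_interaction_index=scenario.true_interaction_index,
                        true_ed50_add=float(ed50_add_true),
                        true_ed50_mixture=truth.ed50,
                        single_fits=single_fits, mixture_fit=mix_fit)
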