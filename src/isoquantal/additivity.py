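"""Loewe (dose-equivalence) additivity for fixed-ratio mixtures.

A fixed-ratio mixture assigns each component a fraction f_i of its *own*
ED50 — a 1:1:1 three-drug design means equal thirds in ED50-fraction units,
not equal mg/kg.  Under dose-equivalence additivity the mixture then behaves
like any single one of its components, and the total mixture dose expected
to protect half the animals is

    ED50_add = sum_i f_i * ED50_i

with SEM propagated across the independent single-drug experiments,

    SEM_add = sqrt( sum_i f_i^2 * SEM_i^2 ).

``n_add`` — the animal count attached to the additive prediction for the
degrees of freedom of the downstream comparison — defaults to the sum of the
components' informative-animal counts, with an explicit override so printed
table values can be used verbatim when raw single-drug data are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .data import SummaryEffectRecord, ValidationError

__all__ = ["MixtureSpec", "AdditivePrediction", "additive_ed50",
           "mixture_composition", "n_add_from_components"]

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class MixtureSpec:
    """Fixed-ratio mixture: component summaries plus ED50-fraction weights.

    ``components`` are (label, SummaryEffectRecord) pairs — fitted
    single-drug results or published summaries.  ``fractions`` must sum to 1;
    equal thirds reproduce the 1:1:1 three-drug design.
    """

    components: tuple[tuple[str, SummaryEffectRecord], ...]
    fractions: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValidationError("a mixture needs >= 2 components")
        if len(self.fractions) != len(self.components):
            raise ValidationError("one fraction per component required")
        if any(f <= 0 for f in self.fractions):
            raise ValidationError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"fractions must sum to 1, got {sum(self.fractions)!r}"
            )
        if not self.label:
            object.__setattr__(
                self, "label", " + ".join(lbl for lbl, _ in self.components)
            )

    @classmethod
    def equal_ratio(cls, records: Sequence[SummaryEffectRecord],
                    label: str = "") -> "MixtureSpec":
        """The field-standard equal fixed-ratio design (1:1:...:1)."""
        k = len(records)
        return cls(tuple((r.label, r) for r in records),
                   tuple(1.0 / k for _ in records), label=label)

    @property
    def records(self) -> tuple[SummaryEffectRecord, ...]:
        return tuple(r for _, r in self.components)


@dataclass(frozen=True)
class AdditivePrediction:
    """Theoretically additive mixture ED50 +/- SEM and its animal count."""

    ed50_add: float
    sem_add: float
    n_add: int


def additive_ed50(spec: MixtureSpec,
                  n_add_override: int | None = None) -> AdditivePrediction:
    """Mass-action additive ED50 for a fixed-ratio mixture.

    ed50_add = sum f_i ED50_i; sem_add by independent error propagation;
    n_add from :func:`n_add_from_components` unless overridden.
    """
    recs = spec.records
    ed50_add = sum(f * r.ed50 for f, r in zip(spec.fractions, recs))
    sem_add = math.sqrt(sum(f**2 * r.sem**2 for f, r in zip(spec.fractions, recs)))
    n_add = n_add_from_components(recs, override=n_add_override)
    return AdditivePrediction(ed50_add=ed50_add, sem_add=sem_add, n_add=n_add)


def mixture_composition(spec: MixtureSpec, total_dose: float) -> dict[str, float]:
    """Split a total mixture dose (mg/kg) into per-component doses.

    Component i receives the share f_i ED50_i / sum_j f_j ED50_j of the
    total, so at total_dose = ED50_add each drug sits at exactly f_i of its
    own ED50.  Shares are dose-independent and sum to the total exactly.
    """
    if not total_dose > 0:
        raise ValidationError(f"total_dose must be positive, got {total_dose}")
    weights = [f * r.ed50 for f, r in zip(spec.fractions, spec.records)]
    wsum = sum(weights)
    return {lbl: total_dose * w / wsum
            for (lbl, _), w in zip(spec.components, weights)}


def n_add_from_components(records: Sequence[SummaryEffectRecord],
                          override: int | None = None) -> int:
    """Animal count for the additive prediction.

    Default convention: sum of the components' counts.  ``override`` accepts
    a published n_add verbatim (used when re-analysing printed tables whose
    derivation of n_add from unpublished single-drug data cannot be redone).
    """
    if override is not None:
        if override < 2:
            raise ValidationError(f"n_add override must be >= 2, got {override}")
        return int(override)
    return int(sum(r.n for r in records))
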