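"""Experimental-vs-additive ED50 comparison and interaction classification.

The isobolographic decision for a fixed-ratio mixture rests on comparing the
experimentally fitted mixture ED50 against the Loewe-additive prediction.
Both come with standard errors of *estimates* (SEMs), so the unpaired
comparison is the Welch form computed directly from the SEMs,

    t  = |ED50_add - ED50_exp| / sqrt(SEM_exp^2 + SEM_add^2)
    df = (SEM_exp^2 + SEM_add^2)^2
         / ( SEM_exp^4/(n_exp - 1) + SEM_add^4/(n_add - 1) )

with a two-sided p from the t distribution at that (non-integer) df.
Significance plus direction classifies the interaction: supra-additive
(synergy) when the mixture is significantly more potent than predicted,
sub-additive (antagonism) when significantly less, additive otherwise.
The interaction index ED50_exp / ED50_add grades the potency of the
interaction (< 1 towards synergy, > 1 towards antagonism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy import stats

from .additivity import AdditivePrediction, MixtureSpec, additive_ed50
from .data import SummaryEffectRecord, ValidationError

__all__ = ["InteractionResult", "welch_t_ed50", "interaction_index",
           "classify_interaction", "analyze_combination",
           "SYNERGY", "ADDITIVITY", "ANTAGONISM"]

SYNERGY = "Synergy"
ADDITIVITY = "Additivity"
ANTAGONISM = "Antagonism"


@dataclass(frozen=True)
class InteractionResult:
    """Full comparison record for one mixture (one table row)."""

    combination_label: str
    ed50_exp: float
    sem_exp: float
    n_exp: int
    ed50_add: float
    sem_add: float
    n_add: int
    t: float
    df: float
    p: float
    classification: str
    interaction_index: float
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        star = ("***" if self.p < 0.001 else "**" if self.p < 0.01
                else "*" if self.p < self.alpha else "")
        return (f"{self.combination_label}: "
                f"ED50_exp = {self.ed50_exp:.2f} ± {self.sem_exp:.2f}{star} "
                f"(n={self.n_exp}) vs ED50_add = "
                f"{self.ed50_add:.2f} ± {self.sem_add:.2f} (n={self.n_add}); "
                f"t_{self.df:.2f} = {self.t:.3f}, p = {self.p:.3g} -> "
                f"{self.classification} (index {self.interaction_index:.2f})")


def welch_t_ed50(exp: SummaryEffectRecord,
                 add: SummaryEffectRecord) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df, and two-sided p for ED50_exp vs
    ED50_add given their SEMs and animal counts (per-record df = n - 1)."""
    va, ve = add.sem**2, exp.sem**2
    if va + ve <= 0:
        raise ValidationError("sum of squared SEMs must be positive")
    t = abs(add.ed50 - exp.ed50) / math.sqrt(ve + va)
    df = (ve + va) ** 2 / (ve**2 / (exp.n - 1) + va**2 / (add.n - 1))
    p = float(min(2.0 * stats.t.sf(t, df), 1.0))
    return t, df, p


def pooled_t_ed50(exp: SummaryEffectRecord,
                  add: SummaryEffectRecord) -> tuple[float, float, float]:
    """Pooled-variance alternative (integer df = n_exp + n_add - 2).

    Not the default: published non-integer dfs in this literature come from
    the Welch form.  Provided for sensitivity checks only.
    """
    df = float(exp.n + add.n - 2)
    t = abs(add.ed50 - exp.ed50) / math.sqrt(exp.sem**2 + add.sem**2)
    p = float(min(2.0 * stats.t.sf(t, df), 1.0))
    return t, df, p


def interaction_index(ed50_exp: float, ed50_add: float) -> float:
    """Interaction index = ED50_exp / ED50_add (exact; report at 2 dp)."""
    if not (ed50_exp > 0 and ed50_add > 0):
        raise ValidationError("ED50 values must be positive")
    return ed50_exp / ed50_add


def classify_interaction(p: float, ed50_exp: float, ed50_add: float,
                         alpha: float = 0.05) -> str:
    """Synergy / Additivity / Antagonism by significance plus direction."""
    if p < alpha:
        return SYNERGY if ed50_exp < ed50_add else ANTAGONISM
    return ADDITIVITY


def analyze_combination(exp: SummaryEffectRecord,
                        additive: MixtureSpec | AdditivePrediction |
                        SummaryEffectRecord,
                        alpha: float = 0.05,
                        n_add_override: int | None = None,
                        label: str | None = None) -> InteractionResult:
    """One-stop comparison: experimental mixture summary vs its additive
    prediction (computed from a MixtureSpec, or supplied directly)."""
    if isinstance(additive, MixtureSpec):
        pred = additive_ed50(additive, n_add_override=n_add_override)
        add_rec = SummaryEffectRecord(f"{additive.label or exp.label} (additive)",
                                      pred.ed50_add, pred.sem_add, pred.n_add)
    elif isinstance(additive, AdditivePrediction):
        add_rec = SummaryEffectRecord(f"{exp.label} (additive)",
                                      additive.ed50_add, additive.sem_add,
                                      additive.n_add)
    else:
        add_rec = additive
    t, df, p = welch_t_ed50(exp, add_rec)
    idx = interaction_index(exp.ed50, add_rec.ed50)
    cls = classify_interaction(p, exp.ed50, add_rec.ed50, alpha=alpha)
    return InteractionResult(
        combination_label=label or exp.label,
        ed50_exp=exp.ed50, sem_exp=exp.sem, n_exp=exp.n,
        ed50_add=add_rec.ed50, sem_add=add_rec.sem, n_add=add_rec.n,
        t=t, df=df, p=p, classification=cls, interaction_index=idx,
        alpha=alpha,
    )


def rank_by_index(results) -> list[InteractionResult]:
    """Descending interaction-index ranking (antagonistic end first)."""
    return sorted(results, key=lambda r: r.interaction_index, reverse=True)
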