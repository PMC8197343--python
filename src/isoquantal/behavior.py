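"""Adverse-effect statistics for behavioural screens.

Two thin wrappers matching how anticonvulsant side-effect data are analysed:
one-way fixed-effects ANOVA for grip strength (mN/g, near-normal continuous
measurements) and the Kruskal-Wallis rank test for rotarod balance times,
which are censored at the 120 s ceiling and typically massively tied there
(often every animal reaches the ceiling, in which case H = 0 and p = 1 by
convention rather than an error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import ValidationError

__all__ = ["BehavioralGroups", "AnovaResult", "KruskalResult",
           "DegenerateDataError", "one_way_anova", "kruskal_wallis"]

ROTAROD_CEILING = 120.0


class DegenerateDataError(ValueError):
    """No within-group variability anywhere: the F ratio is undefined."""


@dataclass(frozen=True)
class BehavioralGroups:
    """Labelled measurement groups (one label per treatment arm)."""

    groups: Mapping[str, Sequence[float]]
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 groups")
        for label, vals in self.groups.items():
            if len(vals) < 2:
                raise ValidationError(
                    f"group {label!r} needs at least 2 observations")
            if self.bounds is not None:
                lo, hi = self.bounds
                arr = np.asarray(vals, dtype=float)
                if arr.min() < lo or arr.max() > hi:
                    raise ValidationError(
                        f"group {label!r} has values outside [{lo}, {hi}]")
        object.__setattr__(self, "groups",
                           {k: tuple(float(x) for x in v)
                            for k, v in self.groups.items()})

    @classmethod
    def rotarod(cls, groups: Mapping[str, Sequence[float]],
                ceiling: float = ROTAROD_CEILING) -> "BehavioralGroups":
        return cls(groups, bounds=(0.0, ceiling))

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for v in self.groups.values()]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float
    all_tied: bool = False


def one_way_anova(groups: BehavioralGroups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across treatment arms.

    Degrees of freedom are (k - 1, N - k); with 7 arms of 8 animals that is
    (6, 49).  Zero pooled within-group variance leaves F undefined and is
    raised as :class:`DegenerateDataError`.
    """
    arrays = groups.arrays()
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        raise DegenerateDataError(
            "zero within-group variance in every group; F is undefined")
    F, p = stats.f_oneway(*arrays)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n_total - k,
                       p=float(p))


def kruskal_wallis(groups: BehavioralGroups) -> KruskalResult:
    """Kruskal-Wallis H with mid-rank tie correction, chi-square p at k-1 df.

    If every observation is identical (e.g. all animals at the rotarod
    ceiling) the tie correction is inapplicable; by convention H = 0 and
    p = 1, with a warning rather than an error.
    """
    arrays = groups.arrays()
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical (complete ties); "
                      "H = 0, p = 1 by convention", stacklevel=2)
        return KruskalResult(H=0.0, df=df, p=1.0, all_tied=True)
    H, p = stats.kruskal(*arrays)
    return KruskalResult(H=float(H), df=df, p=float(p))
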