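"""Data model and readers/writers for quantal dose-response experiments.

The raw observable in a quantal anticonvulsant screen is, per dose group,
the number of animals protected out of the number tested.  A drug (or a
fixed-ratio mixture treated as a single agent) is represented by a
:class:`DoseResponseDataset` holding its dose ladder; summary-level results
(ED50 +/- SEM with an informative-animal count) are carried by
:class:`SummaryEffectRecord` so that published tables can be re-analysed
without raw counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "QuantalDoseGroup",
    "DoseResponseDataset",
    "SummaryEffectRecord",
    "ValidationError",
    "FormatError",
    "read_quantal_csv",
    "write_quantal_csv",
    "read_summary_csv",
    "write_summary_csv",
    "write_report",
]


class ValidationError(ValueError):
    """Input data violate a structural invariant (counts, signs, ranges)."""


class FormatError(ValueError):
    """Input file does not have the expected columns/layout."""


@dataclass(frozen=True)
class QuantalDoseGroup:
    """One dose group: total administered dose (mg/kg), animals tested,
    animals protected."""

    dose: float
    n_subjects: int
    n_responders: int

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"dose must be positive, got {self.dose}")
        if self.n_subjects < 1:
            raise ValidationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0 <= self.n_responders <= self.n_subjects:
            raise ValidationError(
                f"n_responders={self.n_responders} outside [0, {self.n_subjects}]"
            )

    @property
    def proportion(self) -> float:
        return self.n_responders / self.n_subjects


@dataclass(frozen=True)
class DoseResponseDataset:
    """Dose ladder for one subject (a drug, or a mixture treated as one agent).

    For mixtures the dose is the *total* mixture dose in mg/kg; the
    composition is carried separately by a mixture specification, never by
    the dataset itself.  Metadata (pretreatment time, route, vehicle) is
    pass-through and never enters any computation.
    """

    subject_label: str
    groups: tuple[QuantalDoseGroup, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_label:
            raise ValidationError("subject_label must be non-empty")
        groups = tuple(sorted(self.groups, key=lambda g: g.dose))
        doses = [g.dose for g in groups]
        if len(set(doses)) != len(doses):
            raise ValidationError(
                f"duplicate dose levels in dataset {self.subject_label!r}: {doses}"
            )
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(g.dose for g in self.groups)

    @property
    def n_total(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_label": self.subject_label,
                "dose": g.dose,
                "n_subjects": g.n_subjects,
                "n_responders": g.n_responders,
                **self.metadata,
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummaryEffectRecord:
    """Summary-level result: ED50 +/- SEM (mg/kg) and the informative-animal
    count n, as printed in published isobolographic tables."""

    label: str
    ed50: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if not self.ed50 > 0:
            raise ValidationError(f"ed50 must be positive, got {self.ed50}")
        if not self.sem > 0:
            raise ValidationError(f"sem must be positive, got {self.sem}")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")


_QUANTAL_COLUMNS = ("subject_label", "dose", "n_subjects", "n_responders")
_SUMMARY_COLUMNS = ("label", "ed50", "sem", "n")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_quantal_csv(path) -> list[DoseResponseDataset]:
    """Read per-dose protection counts, one dataset per subject_label.

    Columns ``subject_label,dose,n_subjects,n_responders`` are required;
    any further columns are carried as per-dataset metadata (first row wins,
    values stringified).  Groups come back sorted by ascending dose
    regardless of input row order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _QUANTAL_COLUMNS, path)
    extra = [c for c in df.columns if c not in _QUANTAL_COLUMNS]
    datasets = []
    for label, sub in df.groupby("subject_label", sort=True):
        groups = []
        for idx, row in sub.iterrows():
            try:
                groups.append(
                    QuantalDoseGroup(
                        dose=float(row["dose"]),
                        n_subjects=int(row["n_subjects"]),
                        n_responders=int(row["n_responders"]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
        metadata = {c: str(sub.iloc[0][c]) for c in extra if pd.notna(sub.iloc[0][c])}
        datasets.append(
            DoseResponseDataset(subject_label=str(label), groups=tuple(groups),
                                metadata=metadata)
        )
    return datasets


def write_quantal_csv(datasets: Iterable[DoseResponseDataset], path) -> None:
    frames = [d.to_frame() for d in datasets]
    # repr gives the shortest exact representation, so doses round-trip
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=lambda x: repr(float(x)))


def read_summary_csv(path) -> list[SummaryEffectRecord]:
    """Read summary records with columns ``label,ed50,sem,n``."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _SUMMARY_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SummaryEffectRecord(
                    label=str(row["label"]),
                    ed50=float(row["ed50"]),
                    sem=float(row["sem"]),
                    n=int(row["n"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
    return records


def write_summary_csv(records: Iterable[SummaryEffectRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, index=False, float_format=lambda x: repr(float(x)))


def results_frame(results) -> pd.DataFrame:
    """Tabulate interaction results, ranked descending by interaction index."""
    rows = [r.to_dict() for r in results]
    df = pd.DataFrame(rows)
    return df.sort_values("interaction_index", ascending=False).reset_index(drop=True)


def write_report(results, path) -> dict[str, Path]:
    """Write interaction results as CSV + JSON + a plain-text table.

    ``path`` is a stem; ``<stem>.csv``, ``<stem>.json`` and ``<stem>.txt``
    are produced.  Rows are ranked descending by interaction index.  JSON
    keeps full float precision; the text table uses report rounding.
    """
    results = list(results)
    if not results:
        raise ValidationError("write_report: no results to write")
    path = Path(path)
    df = results_frame(results)
    out = {
        "csv": path.with_suffix(".csv"),
        "json": path.with_suffix(".json"),
        "txt": path.with_suffix(".txt"),
    }
    df.to_csv(out["csv"], index=False)
    out["json"].write_text(
        json.dumps(df.to_dict(orient="records"), indent=2) + "\n"
    )
    pretty = df.copy()
    pretty["ED50 exp"] = [
        f"{e:.2f} ± {s:.2f}" for e, s in zip(df.ed50_exp, df.sem_exp)
    ]
    pretty["ED50 add"] = [
        f"{e:.2f} ± {s:.2f}" for e, s in zip(df.ed50_add, df.sem_add)
    ]
    pretty["t-test"] = [
        f"t_{d:.2f} = {t:.3f}; p = {p:.3g}" for t, d, p in zip(df.t, df.df, df.p)
    ]
    pretty["index"] = [f"{i:.2f}" for i in df.interaction_index]
    cols = ["combination_label", "ED50 exp", "n_exp", "ED50 add", "n_add",
            "t-test", "classification", "index"]
    out["txt"].write_text(pretty[cols].to_string(index=False) + "\n")
    return out
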