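"""End-to-end orchestration: fit singles, predict additivity, classify, report.

A :class:`PipelineConfig` declares the inputs (raw quantal CSV and/or
summary CSV), the mixtures to analyse, and the analysis policies (alpha,
n_add convention, informative-count convention).  :func:`run_pipeline`
produces the ranked interaction report, per-combination isobologram-ray
plots, the polygonogram, and a run manifest recording every policy and seed
so a bundle can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .additivity import MixtureSpec
from .data import (SummaryEffectRecord, ValidationError, read_quantal_csv,
                   read_summary_csv, results_frame, write_report)
from .interaction import InteractionResult, analyze_combination, rank_by_index
from .probit import fit_log_probit
from .viz import PolygonogramSpec, render_isobologram, render_polygonogram

__all__ = ["PipelineConfig", "MixtureConfig", "PipelineBundle",
           "run_pipeline", "load_config"]

logger = logging.getLogger("isoquantal")

_N_ADD_POLICIES = ("computed", "supplied")
_INFORMATIVE_POLICIES = ("fitted", "observed")


@dataclass(frozen=True)
class MixtureConfig:
    """One mixture to analyse.

    ``exp`` names the experimental mixture record (fitted from raw data or
    present in the summary CSV).  The additive side is either ``additive``
    (a named summary record, used under the "supplied" n_add policy) or
    ``components`` (+ optional ``fractions``), from which the additive
    prediction is computed.
    """

    label: str
    exp: str
    components: tuple[str, ...] = ()
    fractions: tuple[float, ...] | None = None
    additive: str | None = None
    n_add: int | None = None

    def __post_init__(self) -> None:
        if not self.components and self.additive is None:
            raise ValidationError(
                f"mixture {self.label!r}: give components or an additive record")


@dataclass(frozen=True)
class PipelineConfig:
    mixtures: tuple[MixtureConfig, ...]
    quantal_csv: str | None = None
    summary_csv: str | None = None
    alpha: float = 0.05
    n_add_policy: str = "computed"
    informative_policy: str = "fitted"
    output_dir: str = "isoquantal-output"
    seed: int = 0
    plots: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_add_policy not in _N_ADD_POLICIES:
            raise ValidationError(f"n_add_policy must be one of {_N_ADD_POLICIES}")
        if self.informative_policy not in _INFORMATIVE_POLICIES:
            raise ValidationError(
                f"informative_policy must be one of {_INFORMATIVE_POLICIES}")
        if not self.mixtures:
            raise ValidationError("at least one mixture must be declared")


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    mixtures = tuple(
        MixtureConfig(
            label=m["label"], exp=m.get("exp", m["label"]),
            components=tuple(m.get("components", ())),
            fractions=tuple(m["fractions"]) if m.get("fractions") else None,
            additive=m.get("additive"), n_add=m.get("n_add"),
        )
        for m in raw.pop("mixtures")
    )
    return PipelineConfig(mixtures=mixtures, **raw)


@dataclass(frozen=True)
class PipelineBundle:
    """Everything one run produced, with paths to the files on disk."""

    results: tuple[InteractionResult, ...]
    ranked: tuple[InteractionResult, ...]
    report_paths: dict
    plot_paths: dict
    manifest_path: Path
    output_dir: Path


def _build_registry(config: PipelineConfig) -> dict[str, SummaryEffectRecord]:
    """Label -> summary record, from raw fits and/or the summary CSV."""
    registry: dict[str, SummaryEffectRecord] = {}
    if config.quantal_csv:
        for ds in read_quantal_csv(config.quantal_csv):
            fit = fit_log_probit(ds, informative=config.informative_policy)
            registry[ds.subject_label] = fit.to_summary_record()
            logger.info("fitted %s: ED50 = %.4g ± %.3g mg/kg (n=%d)",
                        ds.subject_label, fit.ed50, fit.sem_ed50,
                        fit.n_informative)
    if config.summary_csv:
        for rec in read_summary_csv(config.summary_csv):
            registry[rec.label] = rec
            logger.info("summary record %s: ED50 = %.4g ± %.3g (n=%d)",
                        rec.label, rec.ed50, rec.sem, rec.n)
    if not registry:
        raise ValidationError("no input records: give quantal_csv or summary_csv")
    return registry


def _analyze_one(mix: MixtureConfig, registry, config) -> InteractionResult:
    try:
        exp = registry[mix.exp]
    except KeyError:
        raise ValidationError(
            f"mixture {mix.label!r}: experimental record {mix.exp!r} not found")
    if mix.additive is not None:
        try:
            additive = registry[mix.additive]
        except KeyError:
            raise ValidationError(
                f"mixture {mix.label!r}: additive record {mix.additive!r} "
                "not found")
        return analyze_combination(exp, additive, alpha=config.alpha,
                                   label=mix.label)
    records = []
    for c in mix.components:
        try:
            records.append(registry[c])
        except KeyError:
            raise ValidationError(
                f"mixture {mix.label!r}: component {c!r} not found")
    if mix.fractions is not None:
        spec = MixtureSpec(tuple((r.label, r) for r in records),
                           mix.fractions, label=mix.label)
    else:
        spec = MixtureSpec.equal_ratio(records, label=mix.label)
    override = mix.n_add if config.n_add_policy == "supplied" else None
    return analyze_combination(exp, spec, alpha=config.alpha,
                               n_add_override=override, label=mix.label)


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Run the full analysis declared by ``config``; see module docstring."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = _build_registry(config)

    results = []
    for mix in config.mixtures:
        res = _analyze_one(mix, registry, config)
        logger.info("%s", res.summary())
        results.append(res)
    ranked = rank_by_index(results)

    report_paths = {k: str(v) for k, v in
                    write_report(ranked, outdir / "interaction_report").items()}

    plot_paths: dict[str, dict] = {}
    if config.plots:
        for res in results:
            stem = outdir / ("isobologram_"
                             + res.combination_label.replace(" ", "_"))
            plot_paths[res.combination_label] = {
                k: str(v) for k, v in render_isobologram(res, stem).items()}
        if len({d for r in results
                for d in r.combination_label.split(" + ")}) >= 3:
            spec = PolygonogramSpec.from_results(results)
            plot_paths["polygonogram"] = {
                k: str(v) for k, v in
                render_polygonogram(spec, outdir / "polygonogram").items()}

    manifest = {
        "package": "isoquantal",
        "version": __version__,
        "alpha": config.alpha,
        "n_add_policy": config.n_add_policy,
        "informative_policy": config.informative_policy,
        "seed": config.seed,
        "inputs": {"quantal_csv": config.quantal_csv,
                   "summary_csv": config.summary_csv},
        "mixtures": [m.label for m in config.mixtures],
        "report": report_paths,
        "plots": plot_paths,
        "ranking": [
            {"combination": r.combination_label,
             "classification": r.classification,
             "interaction_index": round(r.interaction_index, 2)}
            for r in ranked
        ],
        "metadata": config.metadata,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("report bundle written to %s", outdir)
    return PipelineBundle(results=tuple(results), ranked=tuple(ranked),
                          report_paths=report_paths, plot_paths=plot_paths,
                          manifest_path=manifest_path, output_dir=outdir)


def study_results(alpha: float = 0.05) -> list[InteractionResult]:
    """Re-analyse the bundled published six-combination summaries.

    Uses the supplied n_add values (the published convention) and returns
    the six :class:`InteractionResult` rows.
    """
    from .studydata import study_records

    return [analyze_combination(exp, add, alpha=alpha, label=exp.label)
            for exp, add in study_records()]
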