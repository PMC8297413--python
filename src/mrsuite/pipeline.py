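"""One-command orchestration of the full MR workflow.

``run_analysis`` is the library entry point: instrument selection →
harmonization → optional Steiger filtering → the estimator panel →
leave-one-out, for one exposure against one or more outcomes, returning an
:class:`AnalysisReport` per outcome plus a machine-readable manifest with
stage counts and seeds.  ``run_pipeline`` wraps it with file I/O driven by
a :class:`RunConfig` (typically parsed from a YAML file by the CLI).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from . import __version__
from .estimators import METHODS, MethodPanel, estimate_all
from .harmonization import EmptyInstrumentSetError, InstrumentSet, harmonize
from .iv_selection import SelectionConfig, select_biological, select_statistical
from .sensitivity import LeaveOneOutRow, leave_one_out, steiger_filter
from .summary_data import (
    ConfigurationError,
    GeneRegion,
    LDInfo,
    SummaryDataset,
    read_ld_table,
    read_regions_bed,
    read_summary_table,
    write_results_table,
)

logger = logging.getLogger("mrsuite")


@dataclass
class RunConfig:
    """File-driven configuration mirroring the CLI flags.

    ``exposure`` / each entry of ``outcomes`` are mappings with keys
    ``path``, ``column_map``, ``trait_name``, ``trait_type``, ``n``.
    """

    exposure: Mapping
    outcomes: Sequence[Mapping]
    approach: str = "statistical"
    p_threshold: float = 5e-8
    clump_r2: float | None = None
    clump_distance_kb: int = 10_000
    regions_path: str | None = None
    ld_path: str | None = None
    maf_palindrome_limit: float = 0.42
    methods: Sequence[str] = METHODS
    seed: int = 0
    n_boot: int = 1000
    n_sim: int = 1000
    psi: float | None = None
    steiger: bool = True
    output_dir: str = "mr_output"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"invalid run configuration: {exc}") from exc


@dataclass
class AnalysisReport:
    """Everything computed for one exposure-outcome pair."""

    outcome_name: str
    selected_ids: list[str]
    instruments: InstrumentSet
    panel: MethodPanel
    loo: list[LeaveOneOutRow]
    steiger_removed: list[str] = field(default_factory=list)


def _dataset_from_entry(entry: Mapping) -> SummaryDataset:
    return read_summary_table(
        entry["path"],
        entry["column_map"],
        trait_name=entry.get("trait_name", os.path.basename(str(entry["path"]))),
        trait_type=entry.get("trait_type", "continuous"),
        effect_scale=entry.get("effect_scale", "raw-units"),
        sample_size=entry.get("n"),
    )


def run_analysis(
    exposure: SummaryDataset,
    outcomes: Sequence[SummaryDataset],
    ld: LDInfo | None = None,
    regions: Sequence[GeneRegion] | None = None,
    approach: str = "statistical",
    p_threshold: float = 5e-8,
    clump_r2: float | None = None,
    clump_distance_kb: int = 10_000,
    maf_palindrome_limit: float = 0.42,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
    psi: float | None = None,
    steiger: bool = True,
) -> tuple[list[AnalysisReport], dict]:
    """Select instruments once on the exposure, then analyse every outcome.

    Returns the per-outcome reports and a manifest dict recording versions,
    seeds, configuration, and the count surviving each stage (selection ≥
    harmonization ≥ Steiger filtering by construction).
    """
    ld = ld or LDInfo()
    if clump_r2 is None:
        clump_r2 = 0.1 if approach == "biological" else 0.001
    sel_cfg = SelectionConfig(
        p_threshold=p_threshold,
        clump_r2=clump_r2,
        clump_distance_kb=clump_distance_kb,
        approach=approach,
    )
    if approach == "biological":
        if not regions:
            raise ConfigurationError("biological approach requires gene regions")
        selected = select_biological(exposure, regions, ld, sel_cfg)
    else:
        selected = select_statistical(exposure, ld, sel_cfg)
    logger.info("[select] %d instrument(s) selected (%s approach)", len(selected), approach)

    reports: list[AnalysisReport] = []
    stages: dict[str, dict] = {}
    for outcome in outcomes:
        inst = harmonize(exposure, outcome, maf_palindrome_limit, variant_ids=list(selected))
        logger.info("[harmonize] %s: %d retained, %d excluded",
                    outcome.trait_name, len(inst), len(inst.exclusions))
        if len(inst) == 0:
            raise EmptyInstrumentSetError(
                f"no instruments retained for outcome {outcome.trait_name!r}"
            )
        removed: list[str] = []
        if steiger:
            before = set(inst.variant_ids)
            inst, _rows = steiger_filter(inst)
            removed = sorted(before - set(inst.variant_ids))
            logger.info("[steiger] %s: %d removed", outcome.trait_name, len(removed))
            if len(inst) == 0:
                raise EmptyInstrumentSetError(
                    f"Steiger filtering removed every instrument for {outcome.trait_name!r}"
                )
        panel = estimate_all(inst, methods=methods, seed=seed, psi=psi,
                             n_boot=n_boot, n_sim=n_sim)
        loo = leave_one_out(inst) if len(inst) >= 3 else []
        reports.append(AnalysisReport(outcome.trait_name, list(selected), inst, panel, loo,
                                      steiger_removed=removed))
        stages[outcome.trait_name] = {
            "selected": len(selected),
            "harmonized": len(inst) + len(removed),
            "steiger_filtered": len(inst),
            "methods_run": len(panel),
            "method_failures": dict(panel.failures),
        }

    manifest = {
        "package": "mrsuite",
        "version": __version__,
        "seed": seed,
        "approach": approach,
        "p_threshold": p_threshold,
        "clump_r2": clump_r2,
        "clump_distance_kb": clump_distance_kb,
        "maf_palindrome_limit": maf_palindrome_limit,
        "methods": list(methods),
        "steiger": steiger,
        "stages": stages,
    }
    return reports, manifest


def _het_dict(panel: MethodPanel) -> dict:
    out: dict = {}
    for name, het in panel.heterogeneity.items():
        out[name] = {"Q": het.Q, "df": het.df, "pvalue": het.pvalue}
    if panel.pleiotropy is not None:
        out["egger_intercept"] = {
            "intercept": panel.pleiotropy.intercept,
            "se": panel.pleiotropy.se_intercept,
            "pvalue": panel.pleiotropy.pvalue,
        }
    if panel.presso_detail is not None:
        out["presso"] = {
            "global_rss_p": panel.presso_detail.global_rss_p,
            "outliers": panel.presso_detail.outlier_ids,
            "distortion_p": panel.presso_detail.distortion_p,
        }
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """File-in, files-out execution of :func:`run_analysis`.

    Writes, under ``cfg.output_dir``: per-outcome estimate tables,
    diagnostics JSON, exclusion logs, leave-one-out tables, and
    ``manifest.json``.  Returns the manifest.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    exposure = _dataset_from_entry(cfg.exposure)
    outcomes = [_dataset_from_entry(s) for s in cfg.outcomes]
    ld = read_ld_table(cfg.ld_path) if cfg.ld_path else None
    regions = read_regions_bed(cfg.regions_path) if cfg.regions_path else None

    reports, manifest = run_analysis(
        exposure, outcomes, ld=ld, regions=regions, approach=cfg.approach,
        p_threshold=cfg.p_threshold, clump_r2=cfg.clump_r2,
        clump_distance_kb=cfg.clump_distance_kb,
        maf_palindrome_limit=cfg.maf_palindrome_limit, methods=cfg.methods,
        seed=cfg.seed, n_boot=cfg.n_boot, n_sim=cfg.n_sim, psi=cfg.psi,
        steiger=cfg.steiger,
    )

    for rep in reports:
        stem = os.path.join(cfg.output_dir, rep.outcome_name.replace(os.sep, "_"))
        if len(rep.panel):
            write_results_table(rep.panel.estimates, f"{stem}_estimates.tsv")
        with open(f"{stem}_diagnostics.json", "w") as fh:
            json.dump(_het_dict(rep.panel), fh, indent=1)
        with open(f"{stem}_exclusions.json", "w") as fh:
            json.dump(rep.instruments.exclusions, fh, indent=1)
        if rep.loo:
            with open(f"{stem}_leave_one_out.tsv", "w") as fh:
                fh.write("omitted_variant\ttheta\tse\tci_lo\tci_hi\tcrosses_null_changed\n")
                for row in rep.loo:
                    fh.write(
                        f"{row.omitted_variant}\t{row.theta:.10g}\t{row.se:.10g}\t"
                        f"{row.ci_lo:.10g}\t{row.ci_hi:.10g}\t{row.crosses_null_changed}\n"
                    )

    manifest_path = os.path.join(cfg.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("[pipeline] manifest written to %s", manifest_path)
    return manifest
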