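"""End-to-end orchestration: filter -> score -> rank -> report, and the
expression comparisons.  Deterministic given (inputs, config)."""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import ExpressionInputError
from .expression import (
    ExpressionGroup,
    TTestResult,
    ddct_fold_change,
    ks_normality,
    pooled_t_from_summary,
)
from .filters import FilterReport, functional_filter, qc_filter, segregation_filter
from .pedigree import classify_roles_with_carriers, parse_ped
from .scoring import PriorityScore, overall_score_and_rank, ranking_table
from .variants import VariantRecord, read_vcf

logger = logging.getLogger(__name__)


@dataclass
class PrioritizeResult:
    ranked: list  # (VariantRecord, PriorityScore) pairs, best first
    reports: list[FilterReport]
    table: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_prioritize(config: PipelineConfig) -> PrioritizeResult:
    """Run the full prioritization pipeline described by *config*.

    Logs the staged survivor counts in analysis order (called, post-QC,
    post-functional, post-sharing, post-marry-in-exclusion) and, when
    ``config.out_dir`` is set, writes the ranked table, per-stage filter
    reports, and a JSON run manifest.
    """
    if config.vcf is None or config.ped is None:
        raise ValueError("config.vcf and config.ped are required")
    ped = parse_ped(config.ped)
    records = read_vcf(config.vcf, ped=ped, on_sample_mismatch="fail")
    roles = classify_roles_with_carriers(ped, overrides=config.obligate_carriers)

    post_qc, qc_report = qc_filter(records, config.qc)
    post_fn, fn_report = functional_filter(post_qc, config.functional)
    post_seg, seg_report = segregation_filter(
        post_fn,
        ped,
        roles=roles,
        missing_as_compatible=config.missing_as_compatible,
    )
    scored = overall_score_and_rank(post_seg, ped, config.scoring, roles=roles)
    table = ranking_table(scored)
    stage_counts = {
        "called": len(records),
        "post_qc": qc_report.output_count,
        "post_functional": fn_report.output_count,
        "post_sharing": seg_report.substage_counts["sharing"],
        "post_marry_in_exclusion": seg_report.output_count,
    }
    for stage, n in stage_counts.items():
        logger.info("stage %s: %d variants", stage, n)

    reports = [qc_report, fn_report, seg_report]
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        table.to_csv(os.path.join(config.out_dir, "ranked_candidates.tsv"),
                     sep="\t", index=False)
        with open(os.path.join(config.out_dir, "filter_reports.tsv"), "w") as fh:
            for rep in reports:
                fh.write("\n".join(rep.to_lines()) + "\n")
        manifest = {
            "pedprio_version": __version__,
            "inputs": {
                "vcf": {"path": config.vcf, "sha256": _sha256(config.vcf)},
                "ped": {"path": config.ped, "sha256": _sha256(config.ped)},
            },
            "config": config.to_dict(),
            "stage_counts": stage_counts,
        }
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return PrioritizeResult(scored, reports, table, stage_counts)


# ---------------------------------------------------------------------------
# expression comparisons


@dataclass
class ExpressionReport:
    groups: dict[str, ExpressionGroup]
    normality: dict[str, tuple[float, float]]  # label -> (D, p)
    comparisons: list[TTestResult]
    fold_change: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group1": r.group1,
                "group2": r.group2,
                "mean1": self.groups[r.group1].mean,
                "sd1": self.groups[r.group1].sd,
                "n1": self.groups[r.group1].n,
                "mean2": self.groups[r.group2].mean,
                "sd2": self.groups[r.group2].sd,
                "n2": self.groups[r.group2].n,
                "t": r.t,
                "df": r.df,
                "p": r.p,
            }
            for r in self.comparisons
        ]
        return pd.DataFrame(rows)


def run_expression(
    table: Union[str, os.PathLike, pd.DataFrame],
    mode: str = "raw",
    comparisons: Optional[Sequence[tuple[str, str]]] = None,
    welch: bool = False,
) -> ExpressionReport:
    """Group comparisons from a delimited expression table.

    Modes: ``raw`` (sample_id, group, value) — K-S normality per group
    then pairwise pooled t-tests; ``summary`` (group, mean, sd, n) —
    pairwise t-tests only; ``ct`` (sample_id, condition, ct_target,
    ct_reference) — comparative-Ct fold change of the ``sample``
    condition vs. the ``calibrator`` condition.  Pairs default to all
    group pairs in table order.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")

    if mode == "ct":
        required = {"condition", "ct_target", "ct_reference"}
        if not required.issubset(table.columns):
            raise ExpressionInputError(
                f"ct-mode table needs columns {sorted(required)}"
            )
        means = table.groupby("condition")[["ct_target", "ct_reference"]].mean()
        for cond in ("sample", "calibrator"):
            if cond not in means.index:
                raise ExpressionInputError(f"ct table lacks condition {cond!r}")
        fc = ddct_fold_change(
            tuple(means.loc["sample"]), tuple(means.loc["calibrator"])
        )
        return ExpressionReport(groups={}, normality={}, comparisons=[], fold_change=fc)

    groups: dict[str, ExpressionGroup] = {}
    normality: dict[str, tuple[float, float]] = {}
    if mode == "raw":
        if not {"group", "value"}.issubset(table.columns):
            raise ExpressionInputError("raw-mode table needs columns group, value")
        for label, sub in table.groupby("group", sort=False):
            g = ExpressionGroup.from_raw(str(label), sub["value"].to_numpy())
            groups[g.label] = g
            if g.n >= 4:
                normality[g.label] = ks_normality(g.raw_values)
    elif mode == "summary":
        if not {"group", "mean", "sd", "n"}.issubset(table.columns):
            raise ExpressionInputError(
                "summary-mode table needs columns group, mean, sd, n"
            )
        for _, row in table.iterrows():
            g = ExpressionGroup.from_summary(
                str(row["group"]), row["mean"], row["sd"], int(row["n"])
            )
            groups[g.label] = g
    else:
        raise ExpressionInputError(f"unknown table mode {mode!r}")

    labels = list(groups)
    pairs = comparisons if comparisons is not None else list(
        itertools.combinations(labels, 2)
    )
    results = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ExpressionInputError(f"comparison ({a!r}, {b!r}) not in table")
        results.append(pooled_t_from_summary(groups[a], groups[b], welch=welch))
    for r in results:
        logger.info(r.describe())
    return ExpressionReport(groups=groups, normality=normality, comparisons=results)
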