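"""Three-stage variant filter cascade with per-stage rejection ledgers.

Stage 1 (``qc_filter``) removes low-confidence calls on site-level quality
metrics; stage 2 (``functional_filter``) removes synonymous, common, or
poorly supported variants; stage 3 (``segregation_filter``) keeps variants
compatible with a dominant within-family model: carried by every affected
member and every obligate carrier, and absent from all marry-ins.

Every stage returns a :class:`FilterReport` whose counts conserve
(output + rejected = input) and records the *first* failing criterion in a
fixed, documented order, so reports are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .pedigree import Pedigree, RolePartition, classify_roles_with_carriers
from .variants import VariantRecord


@dataclass
class QCThresholds:
    """Site-level hard-filter thresholds (defaults per the study design).

    A record passes when MQ >= min_mapping_quality, MQ0 <= max_mq0_reads,
    DP >= min_site_depth, QUAL >= min_qual and FS <= max_strand_bias_phred
    (all boundaries inclusive on the passing side).  ``mq0_literal``
    switches the MQ0 clause to the literal remove-if-below-4 reading.
    """

    min_mapping_quality: float = 30.0
    max_mq0_reads: int = 4
    min_site_depth: int = 5
    min_qual: float = 50.0
    max_strand_bias_phred: float = 10.0
    mq0_literal: bool = False
    missing_field_passes: bool = False


@dataclass
class FunctionalThresholds:
    """Function/prevalence/support thresholds.

    ``aggregate`` controls whether carrier depth and alt fraction are the
    mean over carrier samples (default) or the per-sample minimum.
    """

    max_db_frequency: float = 0.05
    min_carrier_depth: float = 6.0
    min_alt_fraction: float = 0.30
    drop_synonymous: bool = True
    aggregate: str = "mean"  # "mean" | "min"


@dataclass
class FilterReport:
    """Counts ledger for one filter stage."""

    stage: str
    input_count: int
    output_count: int
    rejections: dict[str, int] = field(default_factory=dict)
    substage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_conserved(self) -> bool:
        return self.output_count + sum(self.rejections.values()) == self.input_count

    def to_lines(self) -> list[str]:
        lines = [
            f"stage\t{self.stage}",
            f"input\t{self.input_count}",
            f"output\t{self.output_count}",
        ]
        for name, n in self.substage_counts.items():
            lines.append(f"after_{name}\t{n}")
        for reason, n in sorted(self.rejections.items()):
            lines.append(f"rejected_{reason}\t{n}")
        return lines


def _apply(records, stage, predicate) -> tuple[list[VariantRecord], FilterReport]:
    passing: list[VariantRecord] = []
    rejections: dict[str, int] = {}
    for r in records:
        reason = predicate(r)
        if reason is None:
            passing.append(r)
        else:
            rejections[reason] = rejections.get(reason, 0) + 1
    report = FilterReport(stage, len(records), len(passing), rejections)
    return passing, report


# ---------------------------------------------------------------------------


def qc_filter(
    records: Sequence[VariantRecord],
    thresholds: Optional[QCThresholds] = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Site-quality hard filter; criteria checked in fixed order (a)-(e)."""
    t = thresholds or QCThresholds()

    def predicate(r: VariantRecord) -> Optional[str]:
        checks = (
            ("low_mapping_quality", r.mapping_quality, lambda x: x >= t.min_mapping_quality),
            (
                "mq0_reads",
                r.mq0_reads,
                (lambda x: x >= t.max_mq0_reads)
                if t.mq0_literal
                else (lambda x: x <= t.max_mq0_reads),
            ),
            ("low_site_depth", r.site_depth, lambda x: x >= t.min_site_depth),
            ("low_qual", r.site_quality, lambda x: x >= t.min_qual),
            ("strand_bias", r.strand_bias_phred, lambda x: x <= t.max_strand_bias_phred),
        )
        for reason, value, ok in checks:
            if value is None:
                if t.missing_field_passes:
                    continue
                return "missing_qc_field"
            if not ok(value):
                return reason
        return None

    return _apply(records, "qc", predicate)


def functional_filter(
    records: Sequence[VariantRecord],
    thresholds: Optional[FunctionalThresholds] = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Drop synonymous, common (> max_db_frequency in any database),
    carrier-less, or poorly supported variants.

    Carrier support: depth and alt-read fraction aggregated over carrier
    samples.  A variant with no recorded frequency is treated as
    frequency 0 (family-specific until observed).
    """
    t = thresholds or FunctionalThresholds()
    if t.aggregate not in ("mean", "min"):
        raise ValueError(f"unknown aggregate mode {t.aggregate!r}")

    def predicate(r: VariantRecord) -> Optional[str]:
        if t.drop_synonymous and r.annotation.consequence_class == "synonymous":
            return "synonymous"
        freq = r.annotation.max_frequency
        if freq is not None and freq > t.max_db_frequency:
            return "common_in_population"
        carrier_calls = [c for c in r.calls.values() if c.is_carrier]
        if not carrier_calls:
            return "no_carrier"
        depths = [c.depth for c in carrier_calls if c.depth is not None]
        fracs = [c.alt_fraction for c in carrier_calls if c.alt_fraction is not None]
        agg = min if t.aggregate == "min" else (lambda xs: sum(xs) / len(xs))
        if depths and agg(depths) < t.min_carrier_depth:
            return "low_carrier_depth"
        if fracs and agg(fracs) < t.min_alt_fraction:
            return "low_alt_fraction"
        return None

    return _apply(records, "functional", predicate)


def segregation_filter(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    roles: Optional[RolePartition] = None,
    obligate_carriers: Iterable[str] = (),
    missing_as_compatible: bool = False,
) -> tuple[list[VariantRecord], FilterReport]:
    """Dominant-model segregation filter, applied as two sequential rules.

    1. *sharing*: every affected member and every obligate carrier is a
       called carrier.  A missing call fails the rule (an uncalled
       required carrier cannot be confirmed to share) unless
       ``missing_as_compatible`` is set.
    2. *marry-in exclusion*: no marry-in is a called carrier; missing
       calls never count as carriers here.

    The report's ``substage_counts`` gives the survivor count after each
    rule separately.
    """
    if roles is None:
        roles = classify_roles_with_carriers(ped, overrides=obligate_carriers)
    elif obligate_carriers:
        roles = RolePartition(
            affected=roles.affected,
            unaffected_blood=roles.unaffected_blood,
            marry_in=roles.marry_in,
            unknown_status=roles.unknown_status,
            obligate_carrier=roles.obligate_carrier | frozenset(obligate_carriers),
        )
    required = roles.affected | roles.obligate_carrier

    def shared(r: VariantRecord) -> bool:
        for sid in required:
            call = r.calls.get(sid)
            carrier = call.is_carrier if call is not None else None
            if carrier is None:
                if not missing_as_compatible:
                    return False
            elif not carrier:
                return False
        return True

    def in_marry_in(r: VariantRecord) -> bool:
        return any(
            (r.calls.get(mid) is not None and r.calls[mid].is_carrier)
            for mid in roles.marry_in
        )

    passing: list[VariantRecord] = []
    rejections: dict[str, int] = {}
    n_shared = 0
    for r in records:
        if not shared(r):
            rejections["not_shared_by_required_carriers"] = (
                rejections.get("not_shared_by_required_carriers", 0) + 1
            )
            continue
        n_shared += 1
        if in_marry_in(r):
            rejections["carried_by_marry_in"] = (
                rejections.get("carried_by_marry_in", 0) + 1
            )
            continue
        passing.append(r)
    report = FilterReport(
        "segregation",
        len(records),
        len(passing),
        rejections,
        substage_counts={
            "sharing": n_shared,
            "marry_in_exclusion": len(passing),
        },
    )
    return passing, report
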