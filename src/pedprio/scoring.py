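"""Multiplicative variant prioritization scores and ranking.

Each candidate variant receives three component scores in (0, 1]:

* ``seg_score_dom`` — dominant-model segregation score,
  pi_a ** (affected non-carriers) * pi_u ** (unaffected blood carriers,
  obligate carriers exempt); 1.0 for a configuration fully consistent
  with dominant transmission.
* ``popu_score`` — tiered population-rarity score from dbSNP membership
  and the maximum recorded database allele frequency.
* ``ann_score`` — functional-consequence score.

The overall score is their product (higher = stronger candidate), and a
null-sharing statistic (1/2)**m (m = blood-member carriers among
non-founders, i.e. informative transmissions) is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .pedigree import Pedigree, RolePartition, classify_roles_with_carriers
from .variants import VariantAnnotation, VariantRecord

logger = logging.getLogger(__name__)


def _default_annotation_map() -> dict[str, float]:
    return {
        "lof_or_damaging": 1.0,
        "nonsynonymous": 0.8,
        "synonymous": 0.01,
        "noncoding": 0.01,
    }


@dataclass
class ScoringConfig:
    """Knobs of the prioritization law.

    The penalty defaults (pi_a = 0.1 per affected non-carrier,
    pi_u = 0.8 per unaffected blood-member carrier) and the population
    tier boundaries (0.001, 0.05) reproduce the component-score patterns
    of the published ranking; they are configurable because the upstream
    scoring tool's internals are cited rather than printed.
    """

    affected_noncarrier_penalty: float = 0.1
    unaffected_carrier_penalty: float = 0.8
    # population tiers, most- to least-extreme
    score_novel: float = 1.0  # absent from dbSNP
    score_no_frequency: float = 0.6  # in dbSNP, no recorded frequency
    score_rare: float = 0.2  # max frequency < rare_threshold
    score_low_frequency: float = 0.02  # otherwise
    rare_threshold: float = 0.001
    annotation_map: dict[str, float] = field(default_factory=_default_annotation_map)

    def __post_init__(self):
        for name in ("affected_noncarrier_penalty", "unaffected_carrier_penalty"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class PriorityScore:
    seg_score_dom: float
    popu_score: float
    ann_score: float
    null_sharing: float
    overall: float
    rank: Optional[int] = None


def combine(ann_score: float, popu_score: float, seg_score_dom: float) -> float:
    """Overall prioritization score: the product of the three components."""
    return ann_score * popu_score * seg_score_dom


def segregation_score_dominant(
    record: VariantRecord,
    roles: RolePartition,
    config: Optional[ScoringConfig] = None,
) -> float:
    """Penalize genotype configurations inconsistent with dominant segregation.

    Missing genotypes contribute no penalty; obligate carriers are exempt
    from the unaffected-carrier penalty (they are *expected* to carry).
    """
    cfg = config or ScoringConfig()
    n_affected_noncarrier = sum(
        1
        for sid in roles.affected
        if (c := record.calls.get(sid)) is not None and c.is_carrier is False
    )
    n_unaffected_carrier = sum(
        1
        for sid in roles.unaffected_blood - roles.obligate_carrier
        if (c := record.calls.get(sid)) is not None and c.is_carrier
    )
    return (
        cfg.affected_noncarrier_penalty**n_affected_noncarrier
        * cfg.unaffected_carrier_penalty**n_unaffected_carrier
    )


def population_score(
    annotation: VariantAnnotation, config: Optional[ScoringConfig] = None
) -> float:
    """Tiered rarity score; frequency taken as the max across databases.

    Frequencies above the functional filter's cut still score (tiering is
    independent of filtering): any recorded frequency >= rare_threshold
    takes the lowest tier.
    """
    cfg = config or ScoringConfig()
    if annotation.dbsnp_id is None:
        return cfg.score_novel
    freq = annotation.max_frequency
    if freq is None:
        return cfg.score_no_frequency
    if freq < cfg.rare_threshold:
        return cfg.score_rare
    return cfg.score_low_frequency


def annotation_score(
    annotation: VariantAnnotation, config: Optional[ScoringConfig] = None
) -> float:
    cfg = config or ScoringConfig()
    cls = annotation.consequence_class
    if cls not in cfg.annotation_map:
        logger.warning("unknown consequence class %r; scoring at lowest tier", cls)
        return min(cfg.annotation_map.values())
    return cfg.annotation_map[cls]


def null_sharing_score(record: VariantRecord, ped: Pedigree) -> float:
    """(1/2)**m with m = blood-member carriers among non-founders.

    Each non-founder blood carrier represents one informative Mendelian
    transmission; under the null of no linkage each transmission passes
    the allele with probability 1/2.
    """
    blood = ped.structural_blood()
    founders = ped.founders
    m = sum(
        1
        for sid, call in record.calls.items()
        if sid in blood and sid not in founders and call.is_carrier
    )
    return 0.5**m


def overall_score_and_rank(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    config: Optional[ScoringConfig] = None,
    roles: Optional[RolePartition] = None,
    obligate_carriers: Iterable[str] = (),
) -> list[tuple[VariantRecord, PriorityScore]]:
    """Score every record and return (record, score) pairs, best first.

    Ties broken by higher population score, then (chrom, pos) for
    determinism.
    """
    cfg = config or ScoringConfig()
    if roles is None:
        roles = classify_roles_with_carriers(ped, overrides=obligate_carriers)
    scored = []
    for r in records:
        seg = segregation_score_dominant(r, roles, cfg)
        popu = population_score(r.annotation, cfg)
        ann = annotation_score(r.annotation, cfg)
        scored.append(
            (
                r,
                PriorityScore(
                    seg_score_dom=seg,
                    popu_score=popu,
                    ann_score=ann,
                    null_sharing=null_sharing_score(r, ped),
                    overall=combine(ann, popu, seg),
                ),
            )
        )
    scored.sort(key=lambda rs: (-rs[1].overall, -rs[1].popu_score, rs[0].chrom, rs[0].pos))
    for i, (_, s) in enumerate(scored, 1):
        s.rank = i
    return scored


def ranking_table(
    scored: Sequence[tuple[VariantRecord, PriorityScore]],
) -> pd.DataFrame:
    """Ranked candidates as a delimited-table-ready DataFrame."""
    rows = []
    for r, s in scored:
        a = r.annotation
        rows.append(
            {
                "rank": s.rank,
                "locus": f"{r.chrom};{r.pos};{r.pos};{r.ref};{r.alt}",
                "gene": a.gene or "-",
                "overall_score": s.overall,
                "ann_score": s.ann_score,
                "popu_score": s.popu_score,
                "seg_score_dom": s.seg_score_dom,
                "seg_score": s.null_sharing,
                "region": a.region_class or "-",
                "dbsnp_id": a.dbsnp_id or "-",
                "variant_type": r.variant_type,
                "max_frequency": a.max_frequency,
            }
        )
    return pd.DataFrame(rows)
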