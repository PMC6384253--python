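"""Synthetic pedigree genotype and expression data by gene-dropping.

The generator emulates the study conditions of a familial mood-disorder
exome analysis: a three-generation, 22-member pedigree (9 affected, one
unaffected obligate carrier, five marry-ins), a planted dominant causal
variant under incomplete penetrance, background variants at Hardy-
Weinberg founder frequencies, read depths in the published per-sample
coverage regime (~46-80x, mean 70x), and normally distributed two-group
expression data.

Gene-dropping draws founder genotypes from population allele frequencies
and transmits alleles down the pedigree by Mendelian rules; the causal
allele is planted heterozygous in a lineal founder, so marry-ins can
never carry it.  Affection is Bernoulli(penetrance) for carriers and
Bernoulli(phenocopy_rate) otherwise.  Everything is deterministic given
the seed, and a truth record retains what was planted so downstream
expectations can be recomputed by brute force.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, parse_ped, write_ped
from .variants import GenotypeCall, VariantAnnotation, VariantRecord, write_vcf
from .errors import PedigreeStructureError


def load_template_pedigree() -> Pedigree:
    """The packaged 22-member, three-generation pedigree template.

    One consistent realization of the study family's described structure
    (9 affected across three generations, five marry-ins, an unaffected
    father of two affected sons whose wife is a marry-in); illustrative,
    not authoritative.
    """
    text = resources.files("pedprio.data").joinpath("family_template.ped").read_text()
    return parse_ped(io.StringIO(text))


@dataclass
class CausalVariantSpec:
    """The planted dominant causal variant."""

    chrom: str = "9"
    pos: int = 128305252
    ref: str = "C"
    alt: str = "G"
    gene: str = "GENE_CAUSAL"
    region_class: str = "exonic"
    consequence_class: str = "lof_or_damaging"
    dbsnp_id: Optional[str] = None
    population_frequency: Optional[float] = None
    founder_id: Optional[str] = None  # None = auto-pick a lineal founder


@dataclass
class SimulationSpec:
    """All knobs of the pedigree-dataset simulation."""

    pedigree: Optional[Pedigree] = None  # None = packaged template
    n_background_variants: int = 500
    background_af_range: tuple[float, float] = (0.01, 0.5)
    background_af: Optional[float] = None  # fixed frequency overrides the range
    causal: CausalVariantSpec = field(default_factory=CausalVariantSpec)
    penetrance: float = 0.9
    phenocopy_rate: float = 0.0
    mean_depth: float = 70.0
    seq_error: float = 0.005
    genotype_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("penetrance", "phenocopy_rate", "seq_error",
                     "genotype_error", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimulationTruth:
    """Ground truth sufficient to recompute downstream expectations."""

    causal_id: str
    carrier_status: dict[str, bool]  # true carriers of the causal allele
    affected: dict[str, bool]  # realized affection statuses
    background_afs: dict[str, float]
    injected_errors: list[tuple[str, str, str]]  # (variant_id, sample, kind)

    def to_lines(self) -> list[str]:
        lines = [f"causal\t{self.causal_id}"]
        for s, c in self.carrier_status.items():
            lines.append(f"carrier\t{s}\t{int(c)}")
        for s, a in self.affected.items():
            lines.append(f"affected\t{s}\t{int(a)}")
        for vid, af in self.background_afs.items():
            lines.append(f"background_af\t{vid}\t{af}")
        for vid, s, kind in self.injected_errors:
            lines.append(f"error\t{vid}\t{s}\t{kind}")
        return lines

    def write(self, dest) -> None:
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                self.write(fh)
                return
        dest.write("\n".join(self.to_lines()) + "\n")


@dataclass
class SimulatedDataset:
    records: list[VariantRecord]
    pedigree: Pedigree  # realized affection statuses
    truth: SimulationTruth

    def write_vcf(self, dest) -> None:
        write_vcf(self.records, dest, samples=self.pedigree.sample_ids)

    def write_ped(self, dest) -> None:
        write_ped(self.pedigree, dest)


# ---------------------------------------------------------------------------


def _drop_order(ped: Pedigree) -> list[Individual]:
    """Members ordered parents-before-children."""
    placed: set[str] = set()
    order: list[Individual] = []
    pending = list(ped.members.values())
    while pending:
        progressed = False
        rest = []
        for ind in pending:
            if all(p in placed for p in ind.parent_ids):
                order.append(ind)
                placed.add(ind.id)
                progressed = True
            else:
                rest.append(ind)
        if not progressed:
            raise PedigreeStructureError("cannot topologically order pedigree")
        pending = rest
    return order


def _gene_drop(
    ped: Pedigree,
    rng: np.random.Generator,
    founder_af: float,
    planted_founder: Optional[str] = None,
) -> dict[str, int]:
    """Allele-count genotypes (0/1/2) by founder HWE draw + transmission."""
    alleles: dict[str, tuple[int, int]] = {}
    for ind in _drop_order(ped):
        if ind.is_founder:
            if planted_founder is not None:
                pair = (1, 0) if ind.id == planted_founder else (0, 0)
            else:
                pair = tuple(rng.binomial(1, founder_af, size=2))
        else:
            inherited = []
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    inherited.append(int(rng.binomial(1, founder_af)))
                else:
                    inherited.append(alleles[pid][rng.integers(0, 2)])
            pair = tuple(inherited)
        alleles[ind.id] = pair
    return {s: a + b for s, (a, b) in alleles.items()}


def _reads_for_genotype(
    g: int, rng: np.random.Generator, mean_depth: float, seq_error: float
) -> tuple[int, int]:
    depth = int(rng.poisson(mean_depth))
    if depth == 0:
        return 0, 0
    p_alt = {0: seq_error, 1: 0.5, 2: 1.0 - seq_error}[g]
    return depth, int(rng.binomial(depth, p_alt))


_GENO_NAME = {0: "hom_ref", 1: "het", 2: "hom_alt"}


def simulate_pedigree_dataset(spec: Optional[SimulationSpec] = None) -> SimulatedDataset:
    """Generate a full (VCF-model, PED, truth) dataset from *spec*."""
    spec = spec or SimulationSpec()
    ped = spec.pedigree or load_template_pedigree()
    rng = np.random.default_rng(spec.seed)
    samples = ped.sample_ids

    # -- causal variant -------------------------------------------------
    founder_id = spec.causal.founder_id
    if founder_id is None:
        blood = ped.structural_blood()
        lineal = sorted(ped.founders & blood)
        if not lineal:
            raise PedigreeStructureError("pedigree template has no lineal founder")
        founder_id = lineal[0]
    elif founder_id not in ped.structural_blood() or founder_id not in ped.founders:
        raise PedigreeStructureError(
            f"causal founder {founder_id!r} is not a lineal founder"
        )
    causal_geno = _gene_drop(ped, rng, 0.0, planted_founder=founder_id)

    # -- realized affection --------------------------------------------
    affected: dict[str, bool] = {}
    members = []
    for ind in ped.members.values():
        p = spec.penetrance if causal_geno[ind.id] > 0 else spec.phenocopy_rate
        aff = bool(rng.random() < p)
        affected[ind.id] = aff
        members.append(replace(ind, affected="affected" if aff else "unaffected"))
    realized = Pedigree(ped.family_id, members)

    # -- genotype matrices ---------------------------------------------
    lo, hi = spec.background_af_range
    genotypes: list[tuple[str, dict[str, int]]] = []
    causal = spec.causal
    causal_id = f"{causal.chrom}:{causal.pos}:{causal.ref}>{causal.alt}"
    genotypes.append((causal_id, causal_geno))
    background_afs: dict[str, float] = {}
    bg_meta: dict[str, tuple[str, int, float]] = {}
    for i in range(spec.n_background_variants):
        af = spec.background_af if spec.background_af is not None else rng.uniform(lo, hi)
        af = float(f"{af:.6g}")  # frequencies kept to 6 significant digits
        chrom = str(1 + i % 22)
        pos = 1_000_000 + 1_000 * i
        vid = f"{chrom}:{pos}:A>G"
        genotypes.append((vid, _gene_drop(ped, rng, af)))
        background_afs[vid] = af
        bg_meta[vid] = (chrom, pos, af)

    # -- reads, noise, records -----------------------------------------
    region_pool = ("intronic", "exonic", "intergenic", "UTR3", "UTR5")
    region_probs = (0.30, 0.49, 0.08, 0.07, 0.06)
    injected: list[tuple[str, str, str]] = []
    records: list[VariantRecord] = []
    for vid, geno in genotypes:
        is_causal = vid == causal_id
        if is_causal:
            ann = VariantAnnotation(
                gene=causal.gene,
                region_class=causal.region_class,
                consequence_class=causal.consequence_class,
                dbsnp_id=causal.dbsnp_id,
                db_frequencies=(
                    {"1000G": float(f"{causal.population_frequency:.6g}")}
                    if causal.population_frequency is not None
                    else {}
                ),
            )
            chrom, pos, ref, alt = causal.chrom, causal.pos, causal.ref, causal.alt
        else:
            chrom, pos, af = bg_meta[vid]
            region = region_pool[int(rng.choice(len(region_pool), p=region_probs))]
            if region == "exonic":
                csq = "synonymous" if rng.random() < 0.5 else "nonsynonymous"
            else:
                csq = "noncoding"
            ann = VariantAnnotation(
                gene=f"BG{vid.split(':')[1]}" if region in ("exonic", "intronic") else None,
                region_class=region,
                consequence_class=csq,
                dbsnp_id=f"rs9{pos}",
                db_frequencies={"1000G": af},
            )
            ref, alt = "A", "G"
        calls: dict[str, GenotypeCall] = {}
        for s in samples:
            g = geno[s]
            depth, alt_reads = _reads_for_genotype(
                g, rng, spec.mean_depth, spec.seq_error
            )
            name = _GENO_NAME[g]
            if spec.genotype_error > 0 and rng.random() < spec.genotype_error:
                name = "het" if name == "hom_ref" else "hom_ref"
                injected.append((vid, s, "genotype_flip"))
            if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                name = "missing"
                injected.append((vid, s, "missing"))
            calls[s] = GenotypeCall(s, name, depth, min(alt_reads, depth))
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                site_quality=1000.0,
                mapping_quality=60.0,
                mq0_reads=0,
                site_depth=int(sum(c.depth or 0 for c in calls.values())),
                strand_bias_phred=0.0,
                annotation=ann,
                calls=calls,
            )
        )

    truth = SimulationTruth(
        causal_id=causal_id,
        carrier_status={s: causal_geno[s] > 0 for s in samples},
        affected=affected,
        background_afs=background_afs,
        injected_errors=injected,
    )
    return SimulatedDataset(records=records, pedigree=realized, truth=truth)


# ---------------------------------------------------------------------------


def simulate_expression(
    groups: Sequence[tuple[str, float, float, int]],
    seed: int = 0,
    exact_moments: bool = False,
) -> pd.DataFrame:
    """Two-group (or k-group) normal expression draws.

    *groups* is a sequence of (label, mean, sd, n).  With
    ``exact_moments=True`` each group's draws are affinely rescaled so the
    sample mean and SD equal the specification exactly (useful for
    reconstructing raw data compatible with published summaries).
    Returns a tidy table (sample_id, group, value).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd, n in groups:
        if n < 2:
            raise ValueError(f"group {label!r}: need n >= 2, got {n}")
        if sd <= 0:
            raise ValueError(f"group {label!r}: sd must be > 0, got {sd}")
        x = rng.normal(mean, sd, size=int(n))
        if exact_moments:
            x = mean + (x - x.mean()) * (sd / x.std(ddof=1))
        for i, v in enumerate(x, 1):
            rows.append({"sample_id": f"{label}_{i:02d}", "group": label, "value": v})
    return pd.DataFrame(rows)
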