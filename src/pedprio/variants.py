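"""Variant data model and annotated multi-sample VCF I/O.

The pipeline consumes a *pre-annotated* VCF: gene, genomic region class,
functional consequence class, dbSNP id and per-database allele frequencies
must already be present as INFO keys.  The strict INFO schema is::

    MQ      Float   RMS mapping quality
    MQ0     Integer reads with mapping quality zero
    DP      Integer approximate site read depth
    FS      Float   phred-scaled strand-bias (Fisher's exact) score
    GENE    String  gene symbol
    REGION  String  genomic region class (closed vocabulary, REGION_CLASSES)
    CSQCLASS String functional consequence class (CONSEQUENCE_CLASSES)
    DBSNP   String  dbSNP identifier
    AF_<db> Float   alternate-allele frequency in database <db>

Per-sample FORMAT fields GT, DP and AD are required.  Multi-allelic sites
are split into one record per ALT allele on read.

Floats round-trip through cyvcf2 as 32-bit; all floats are therefore
normalised to 6 significant digits on read so that read-write-read is an
exact identity on the retained fields.
"""

from __future__ import annotations

import io
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from cyvcf2 import VCF

from .errors import SampleMismatchError, VCFParseError
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

#: Region vocabulary (genomic region classes used for tabulation).
REGION_CLASSES = (
    "exonic",
    "intronic",
    "splicing",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "ncRNA_splicing",
    "UTR5",
    "UTR3",
    "upstream",
    "downstream",
    "intergenic",
    "exonic_splicing",
    "upstream_downstream",
    "UTR5_UTR3",
)

CONSEQUENCE_CLASSES = ("lof_or_damaging", "nonsynonymous", "synonymous", "noncoding")

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


def _f6(x) -> float:
    """Normalise a float to 6 significant digits (float32-safe round trip)."""
    return float(f"{float(x):.6g}")


@dataclass
class GenotypeCall:
    sample_id: str
    genotype: str  # hom_ref | het | hom_alt | missing
    depth: Optional[int] = None
    alt_reads: Optional[int] = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if (
            self.depth is not None
            and self.alt_reads is not None
            and self.alt_reads > self.depth
        ):
            raise ValueError(
                f"{self.sample_id}: alt_reads {self.alt_reads} exceeds depth {self.depth}"
            )

    @property
    def is_carrier(self) -> Optional[bool]:
        """At least one alt allele; None when the genotype is missing."""
        if self.genotype == "missing":
            return None
        return self.genotype in ("het", "hom_alt")

    @property
    def alt_fraction(self) -> Optional[float]:
        """Variant allele fraction (alt reads / depth)."""
        if not self.depth or self.alt_reads is None:
            return None
        return self.alt_reads / self.depth


@dataclass
class VariantAnnotation:
    gene: Optional[str] = None
    region_class: Optional[str] = None
    consequence_class: Optional[str] = None
    dbsnp_id: Optional[str] = None
    db_frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.region_class is not None and self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        for db, f in self.db_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for db {db!r} outside [0,1]")

    @property
    def max_frequency(self) -> Optional[float]:
        """Maximum recorded frequency across databases, None when none recorded."""
        return max(self.db_frequencies.values()) if self.db_frequencies else None


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_quality: Optional[float] = None
    mapping_quality: Optional[float] = None
    mq0_reads: Optional[int] = None
    site_depth: Optional[int] = None
    strand_bias_phred: Optional[float] = None
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def variant_type(self) -> str:
        return "indel" if len(self.ref) != len(self.alt) else "SNV"

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def carriers(self) -> list[str]:
        return [s for s, c in self.calls.items() if c.is_carrier]


# ---------------------------------------------------------------------------
# reading


def _geno_for_allele(alleles: Sequence[int], allele_index: int) -> str:
    if any(a < 0 for a in alleles):
        return "missing"
    hits = sum(1 for a in alleles if a == allele_index)
    if hits == 0:
        return "hom_ref"
    if hits >= len(alleles):
        return "hom_alt"
    return "het"


def read_vcf(
    source: Union[str, os.PathLike, io.TextIOBase],
    ped: Optional[Pedigree] = None,
    on_sample_mismatch: str = "warn",
) -> list[VariantRecord]:
    """Read an annotated VCF into :class:`VariantRecord` objects.

    Multi-allelic sites yield one record per ALT allele.  When *ped* is
    given, its sample set is reconciled against the VCF header
    (``on_sample_mismatch`` = ``"warn"`` or ``"fail"``).
    """
    if isinstance(source, io.TextIOBase):
        with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return read_vcf(path, ped=ped, on_sample_mismatch=on_sample_mismatch)
        finally:
            os.unlink(path)

    try:
        vcf = VCF(os.fspath(source))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise VCFParseError(f"cannot open VCF {source!s}: {exc}") from exc

    samples = list(vcf.samples)
    if ped is not None:
        missing = sorted(set(ped.sample_ids) - set(samples))
        extra = sorted(set(samples) - set(ped.sample_ids))
        if missing or extra:
            msg = (
                f"sample mismatch between VCF and pedigree: "
                f"absent from VCF {missing}, absent from pedigree {extra}"
            )
            if on_sample_mismatch == "fail":
                raise SampleMismatchError(msg)
            logger.warning(msg)

    records: list[VariantRecord] = []
    for v in vcf:
        info = dict(v.INFO)
        try:
            dp_fmt = v.format("DP")
            ad_fmt = v.format("AD")
        except Exception as exc:
            raise VCFParseError(
                f"{v.CHROM}:{v.POS}: cannot read FORMAT fields: {exc}"
            ) from exc
        n_alt = len(v.ALT)
        for ai, alt in enumerate(v.ALT):
            freqs = {}
            for key, val in info.items():
                if key.startswith("AF_") and val is not None:
                    if isinstance(val, tuple):
                        val = val[ai] if ai < len(val) else None
                    if val is not None:
                        freqs[key[3:]] = _f6(val)
            ann = VariantAnnotation(
                gene=info.get("GENE"),
                region_class=info.get("REGION"),
                consequence_class=info.get("CSQCLASS"),
                dbsnp_id=info.get("DBSNP"),
                db_frequencies=freqs,
            )
            calls: dict[str, GenotypeCall] = {}
            for si, sample in enumerate(samples):
                alleles = v.genotypes[si][:-1]
                geno = _geno_for_allele(alleles, ai + 1)
                depth = None
                if dp_fmt is not None and dp_fmt[si][0] >= 0:
                    depth = int(dp_fmt[si][0])
                alt_reads = None
                if ad_fmt is not None and ad_fmt[si][ai + 1] >= 0:
                    alt_reads = int(ad_fmt[si][ai + 1])
                if depth is None and ad_fmt is not None:
                    vals = [int(x) for x in ad_fmt[si][: n_alt + 1] if x >= 0]
                    depth = sum(vals) if vals else None
                calls[sample] = GenotypeCall(sample, geno, depth, alt_reads)
            mq0 = info.get("MQ0")
            dp = info.get("DP")
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    site_quality=_f6(v.QUAL) if v.QUAL is not None else None,
                    mapping_quality=_f6(info["MQ"]) if "MQ" in info else None,
                    mq0_reads=int(mq0) if mq0 is not None else None,
                    site_depth=int(dp) if dp is not None else None,
                    strand_bias_phred=_f6(info["FS"]) if "FS" in info else None,
                    annotation=ann,
                    calls=calls,
                )
            )
    return records


# ---------------------------------------------------------------------------
# writing

_GT_STRINGS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}

_INFO_HEADER = [
    ('MQ', 'Float', 'RMS mapping quality'),
    ('MQ0', 'Integer', 'Reads with mapping quality zero'),
    ('DP', 'Integer', 'Approximate read depth'),
    ('FS', 'Float', 'Phred-scaled strand bias p-value'),
    ('GENE', 'String', 'Gene symbol'),
    ('REGION', 'String', 'Genomic region class'),
    ('CSQCLASS', 'String', 'Functional consequence class'),
    ('DBSNP', 'String', 'dbSNP identifier'),
]


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(
    records: Sequence[VariantRecord],
    dest: Union[str, os.PathLike, io.TextIOBase],
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Write records as VCF v4.2 text (deterministic field ordering).

    Inverse of :func:`read_vcf` on the retained fields.  All records must
    share one sample set; *samples* overrides the column order.
    """
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w") as fh:
            write_vcf(records, fh, samples=samples)
            return

    if samples is None:
        samples = list(records[0].calls) if records else []
    db_names = sorted({db for r in records for db in r.annotation.db_frequencies})

    dest.write("##fileformat=VCFv4.2\n")
    dest.write("##source=pedprio\n")
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.chrom)
    for chrom in seen:
        dest.write(f"##contig=<ID={chrom}>\n")
    for key, typ, desc in _INFO_HEADER:
        dest.write(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n'
        )
    for db in db_names:
        dest.write(
            f'##INFO=<ID=AF_{db},Number=1,Type=Float,'
            f'Description="Alternate allele frequency in {db}">\n'
        )
    dest.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    dest.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    dest.write(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">\n'
    )
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    dest.write("\t".join(cols + list(samples)) + "\n")

    for r in records:
        info_parts = []
        a = r.annotation
        if r.mapping_quality is not None:
            info_parts.append(f"MQ={_fmt_float(r.mapping_quality)}")
        if r.mq0_reads is not None:
            info_parts.append(f"MQ0={r.mq0_reads}")
        if r.site_depth is not None:
            info_parts.append(f"DP={r.site_depth}")
        if r.strand_bias_phred is not None:
            info_parts.append(f"FS={_fmt_float(r.strand_bias_phred)}")
        if a.gene is not None:
            info_parts.append(f"GENE={a.gene}")
        if a.region_class is not None:
            info_parts.append(f"REGION={a.region_class}")
        if a.consequence_class is not None:
            info_parts.append(f"CSQCLASS={a.consequence_class}")
        if a.dbsnp_id is not None:
            info_parts.append(f"DBSNP={a.dbsnp_id}")
        for db in db_names:
            if db in a.db_frequencies:
                info_parts.append(f"AF_{db}={_fmt_float(a.db_frequencies[db])}")
        info = ";".join(info_parts) if info_parts else "."
        qual = _fmt_float(r.site_quality) if r.site_quality is not None else "."
        sample_fields = []
        for s in samples:
            c = r.calls.get(s)
            if c is None:
                sample_fields.append("./.:.:.")
                continue
            dp = str(c.depth) if c.depth is not None else "."
            if c.depth is not None and c.alt_reads is not None:
                ad = f"{c.depth - c.alt_reads},{c.alt_reads}"
            else:
                ad = "."
            sample_fields.append(f"{_GT_STRINGS[c.genotype]}:{dp}:{ad}")
        dest.write(
            "\t".join(
                [r.chrom, str(r.pos), ".", r.ref, r.alt, qual, ".", info, "GT:DP:AD"]
                + sample_fields
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# tabulation


def tabulate_regions(
    records: Iterable[VariantRecord],
) -> dict[str, tuple[int, float]]:
    """Count records per region class, with percent of total.

    Region-class distribution table: counts sum to the total and percents
    to 100 up to rounding; empty input gives an empty table.
    """
    counts: dict[str, int] = {}
    total = 0
    for r in records:
        region = r.annotation.region_class or "unclassified"
        counts[region] = counts.get(region, 0) + 1
        total += 1
    return {
        region: (n, 100.0 * n / total)
        for region, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
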