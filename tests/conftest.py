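import io
import textwrap

import pytest

from pedprio import (
    GenotypeCall,
    VariantAnnotation,
    VariantRecord,
    load_template_pedigree,
)

TEMPLATE_AFFECTED = {"A06", "A08", "A12", "A15", "A17", "A18", "A21", "A23", "A25"}
TEMPLATE_MARRY_INS = {"A09", "A10", "A11", "A13", "A14"}


@pytest.fixture(scope="session")
def template_ped():
    """The packaged 22-member family pedigree (9 affected, 5 marry-ins)."""
    return load_template_pedigree()


@pytest.fixture
def make_record():
    """Factory for VariantRecords with passing QC defaults."""

    def _make(
        carriers=(),
        samples=None,
        chrom="1",
        pos=100,
        ref="A",
        alt="G",
        mq=60.0,
        mq0=0,
        dp=100,
        qual=500.0,
        fs=1.0,
        gene="GENE1",
        region="exonic",
        consequence="nonsynonymous",
        dbsnp=None,
        freqs=None,
        depth=70,
        alt_reads=35,
        missing=(),
    ):
        if samples is None:
            samples = sorted(set(carriers) | set(missing)) or ["S1"]
        calls = {}
        for s in samples:
            if s in missing:
                calls[s] = GenotypeCall(s, "missing")
            elif s in carriers:
                calls[s] = GenotypeCall(s, "het", depth, alt_reads)
            else:
                calls[s] = GenotypeCall(s, "hom_ref", depth, 0)
        return VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            site_quality=qual,
            mapping_quality=mq,
            mq0_reads=mq0,
            site_depth=dp,
            strand_bias_phred=fs,
            annotation=VariantAnnotation(
                gene=gene,
                region_class=region,
                consequence_class=consequence,
                dbsnp_id=dbsnp,
                db_frequencies=freqs or {},
            ),
            calls=calls,
        )

    return _make


TOY_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##contig=<ID=2>
    ##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
    ##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with mapping quality zero">
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
    ##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias p-value">
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
    ##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region class">
    ##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Functional consequence class">
    ##INFO=<ID=DBSNP,Number=1,Type=String,Description="dbSNP identifier">
    ##INFO=<ID=AF_1000G,Number=A,Type=Float,Description="Alternate allele frequency in 1000G">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    1\t100\t.\tA\tG\t900\t.\tMQ=60;MQ0=0;DP=210;FS=0.5;GENE=G1;REGION=exonic;CSQCLASS=nonsynonymous;DBSNP=rs1;AF_1000G=0.01\tGT:DP:AD\t0/1:70:35,35\t0/0:71:71,0\t1/1:69:1,68
    1\t200\t.\tC\tT\t800\t.\tMQ=55;MQ0=1;DP=190;FS=2;GENE=G2;REGION=intronic;CSQCLASS=noncoding\tGT:DP:AD\t0/0:60:60,0\t0/1:65:33,32\t./.:.:.
    2\t300\t.\tG\tA,T\t700\t.\tMQ=50;MQ0=2;DP=180;FS=3;GENE=G3;REGION=exonic;CSQCLASS=synonymous;AF_1000G=0.2,0.002\tGT:DP:AD\t0/1:62:31,31,0\t1/2:64:2,30,32\t0/2:66:33,1,32
    """
)


@pytest.fixture
def toy_vcf_stream():
    return io.StringIO(TOY_VCF)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive re-statements of the
# filter predicates; they never call the implementation).


def brute_qc_pass(r, *, min_mq=30.0, max_mq0=4, min_dp=5, min_qual=50.0, max_fs=10.0):
    for v in (r.mapping_quality, r.mq0_reads, r.site_depth, r.site_quality,
              r.strand_bias_phred):
        if v is None:
            return False
    return (
        r.mapping_quality >= min_mq
        and r.mq0_reads <= max_mq0
        and r.site_depth >= min_dp
        and r.site_quality >= min_qual
        and r.strand_bias_phred <= max_fs
    )


def brute_functional_pass(r, *, max_freq=0.05, min_depth=6.0, min_frac=0.30):
    if r.annotation.consequence_class == "synonymous":
        return False
    if r.annotation.db_frequencies and max(r.annotation.db_frequencies.values()) > max_freq:
        return False
    carriers = [
        c for c in r.calls.values() if c.genotype in ("het", "hom_alt")
    ]
    if not carriers:
        return False
    depths = [c.depth for c in carriers if c.depth is not None]
    if depths and sum(depths) / len(depths) < min_depth:
        return False
    fracs = [c.alt_reads / c.depth for c in carriers if c.depth]
    if fracs and sum(fracs) / len(fracs) < min_frac:
        return False
    return True


def brute_segregation_pass(r, required, marry_ins):
    for sid in required:
        c = r.calls.get(sid)
        if c is None or c.genotype not in ("het", "hom_alt"):
            return False
    for sid in marry_ins:
        c = r.calls.get(sid)
        if c is not None and c.genotype in ("het", "hom_alt"):
            return False
    return True
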