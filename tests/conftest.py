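import sys
from pathlib import Path

import pytest

from exoburden.model import (
    AnnotatedVariant,
    Cohort,
    Consequence,
    PredictorCall,
    Verdict,
    Zygosity,
)

sys.path.insert(0, str(Path(__file__).parent))  # make tests.oracle importable


_COUNTER = {"pos": 0}


def make_variant(
    gene="GENEA",
    consequence=Consequence.MISSENSE,
    verdicts=("deleterious", "deleterious", "deleterious"),
    maf=0.001,
    population="NFE",
    carriers=("S1",),
    zygosity=Zygosity.HETEROZYGOUS,
    pos=None,
    qual=60.0,
    depth=40,
    mq=50.0,
    **kw,
):
    """Small factory for hand-built variants with sensible passing defaults."""
    _COUNTER["pos"] += 17
    frequencies = {} if maf is None else {population: maf}
    frequencies.update(kw.pop("extra_freqs", {}))
    genotypes = {s: zygosity for s in carriers}
    genotypes.update(kw.pop("extra_genotypes", {}))
    return AnnotatedVariant(
        chrom=kw.pop("chrom", gene or "chrU"),
        pos=pos if pos is not None else _COUNTER["pos"],
        ref=kw.pop("ref", "A"),
        alt=kw.pop("alt", "G"),
        site_quality=qual,
        read_depth=depth,
        mapping_quality=mq,
        gene=gene,
        consequence=consequence,
        frequencies=frequencies,
        predictor_calls=[
            PredictorCall(f"p{i}", Verdict(v)) for i, v in enumerate(verdicts)
        ],
        genotypes=genotypes,
        **kw,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def small_cohort():
    """Five-sample cohort with a mix of passing and failing variants."""
    samples = [f"S{i}" for i in range(1, 6)]
    variants = [
        make_variant(gene="GJB2", carriers=("S1",)),
        make_variant(gene="GJB2", carriers=("S1", "S2")),
        make_variant(gene="MYO6", consequence=Consequence.STOP_GAINED,
                     verdicts=(), carriers=("S1",)),
        make_variant(gene="NEDD4", maf=0.2, carriers=("S3",)),          # fails rarity
        make_variant(gene="ZAN", consequence=Consequence.SYNONYMOUS,
                     carriers=("S4",)),                                  # fails consequence
        make_variant(gene="TTN", verdicts=("benign", "benign", "deleterious"),
                     carriers=("S5",)),                                  # fails vote
        make_variant(gene="WFS1", qual=10.0, carriers=("S2",)),          # fails quality
    ]
    return Cohort(samples=samples, variants=variants)


MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=PRED,Number=1,Type=String,Description="Predictor verdicts">
##INFO=<ID=AF_NFE,Number=1,Type=Float,Description="MAF NFE">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t100\trs1\tA\tG\t50\t.\tDP=30;MQ=50;GENE=GJB2;CSQ=missense;PRED=p1:deleterious|p2:benign;AF_NFE=0.01\tGT\t0/1
chr1\t200\t.\tC\tG,T\t60\t.\tDP=40;MQ=55;GENE=MYO6;CSQ=missense;AF_NFE=0.002\tGT\t1/2
chr1\t300\t.\tT\tC\t70\t.\tDP=35;MQ=52;GENE=WFS1;CSQ=stop_gained;AF_NFE=0.0001\tGT\t1/1
"""


@pytest.fixture
def multiallelic_vcf(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(MULTIALLELIC_VCF)
    return path
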