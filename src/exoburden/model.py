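"""Domain types for annotated exome cohorts.

The central object is :class:`AnnotatedVariant`: one called variant (one
alternate allele at one site) carrying its call-quality metrics, gene
assignment, consequence class, per-population minor allele frequencies and
the verdicts of in-silico deleteriousness predictors. A :class:`Cohort`
bundles the variants of a multi-sample study together with per-sample
genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping


class Consequence(str, Enum):
    """Controlled vocabulary of variant consequence classes.

    The five most severe classes (transcript ablation, essential splice
    site, frameshift indel, stop gain, start loss) are treated as
    loss-of-function (LoF): they are expected to abolish the gene product
    and count as pathogenic without any predictor support.
    """

    TRANSCRIPT_ABLATION = "transcript_ablation"
    ESSENTIAL_SPLICE_SITE = "essential_splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    STOP_GAINED = "stop_gained"
    START_LOST = "start_lost"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER = "other"
    UNKNOWN = "unknown"

    @property
    def is_lof(self) -> bool:
        return self in LOF_CONSEQUENCES


LOF_CONSEQUENCES = frozenset(
    {
        Consequence.TRANSCRIPT_ABLATION,
        Consequence.ESSENTIAL_SPLICE_SITE,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.STOP_GAINED,
        Consequence.START_LOST,
    }
)


class Verdict(str, Enum):
    """Three-valued deleteriousness call from one predictor."""

    DELETERIOUS = "deleterious"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class Zygosity(str, Enum):
    REFERENCE = "reference"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_ALT = "homozygous_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        """A missing genotype never counts as a carrier."""
        return self in (Zygosity.HETEROZYGOUS, Zygosity.HOMOZYGOUS_ALT)


@dataclass(frozen=True)
class PredictorCall:
    predictor_name: str
    verdict: Verdict


@dataclass(frozen=True)
class GenotypeCall:
    """Zygosity of one sample at one variant."""

    sample_id: str
    zygosity: Zygosity


VariantKey = tuple[str, int, str, str]


@dataclass
class AnnotatedVariant:
    """One called variant: one alternate allele at one site.

    ``frequencies`` maps population labels (e.g. the primary reference
    population, a fallback population, other populations) to minor allele
    frequencies in [0, 1]; missing entries are allowed and mean "no data
    recorded". ``predictor_calls`` may be empty, e.g. for LoF variants
    where missense predictors do not apply. Quality metrics may be None
    when the caller did not report them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_quality: float | None = None
    read_depth: int | None = None
    mapping_quality: float | None = None
    gene: str = ""
    consequence: Consequence = Consequence.UNKNOWN
    frequencies: dict[str, float] = field(default_factory=dict)
    predictor_calls: list[PredictorCall] = field(default_factory=list)
    variant_id: str | None = None
    genotypes: dict[str, Zygosity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        for pop, maf in self.frequencies.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"frequency {maf!r} for {pop} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def carriers(self) -> list[str]:
        """Samples carrying the alternate allele (het or hom)."""
        return [s for s, z in self.genotypes.items() if z.is_carrier]

    def zygosity_of(self, sample_id: str) -> Zygosity:
        return self.genotypes.get(sample_id, Zygosity.REFERENCE)


@dataclass(frozen=True)
class GenePanel:
    """A named, curated gene list with role flags.

    ``dominant_subset`` marks genes where a single damaging allele is
    expected to suffice. ``is_exclusion_list`` marks panels of
    platform-artifact-prone genes whose hits are flagged, never removed.
    """

    name: str
    genes: frozenset[str]
    dominant_subset: frozenset[str] = frozenset()
    is_exclusion_list: bool = False

    def __post_init__(self) -> None:
        if not self.dominant_subset <= self.genes:
            extra = sorted(self.dominant_subset - self.genes)
            raise ValueError(f"dominant subset not contained in panel: {extra}")

    @classmethod
    def from_symbols(
        cls,
        name: str,
        genes,
        dominant_subset=(),
        is_exclusion_list: bool = False,
    ) -> "GenePanel":
        """Build a panel from raw symbols: upper-cased, deduplicated."""
        norm = frozenset(g.strip().upper() for g in genes if g.strip())
        dom = frozenset(g.strip().upper() for g in dominant_subset if g.strip())
        return cls(name=name, genes=norm, dominant_subset=dom,
                   is_exclusion_list=is_exclusion_list)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CohortManifest:
    """Assignment of each sample to a phenotype subgroup.

    Subgroup labels are free-form; the study design uses Dominant,
    Recessive, Metabolic and Sensory.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for sample, subgroup in self.assignments.items():
            if not sample or not subgroup:
                raise ValueError("sample_id and subgroup must be non-empty")

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def subgroup_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def members(self, subgroup: str) -> list[str]:
        out = [s for s, g in self.assignments.items() if g == subgroup]
        if not out:
            raise KeyError(f"unknown subgroup {subgroup!r}")
        return out

    def subgroup_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.assignments.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def subgroups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g)
        return list(seen)


@dataclass
class Cohort:
    """A multi-sample collection of annotated variants with genotypes."""

    samples: list[str]
    variants: list[AnnotatedVariant]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[AnnotatedVariant]:
        return iter(self.variants)

    def variants_of(self, sample_id: str) -> list[AnnotatedVariant]:
        """Variants carried (het or hom) by one sample."""
        if sample_id not in self.samples:
            raise KeyError(f"unknown sample {sample_id!r}")
        return [v for v in self.variants if v.zygosity_of(sample_id).is_carrier]
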