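"""Cohort-level discovery analyses on filtered variants.

Given a cohort filtered at an appropriate rarity tier these analyses
look for the signals a gene-discovery study reads off directly:

* genes hit in *every* member of a phenotype subgroup (common-variant
  sharing, run at the low-stringency tier);
* genes hit in two or more individuals, and identical variants recurring
  across individuals (run at the very-rare tier);
* apparently-homozygous very rare variants (the "apparently" caveat:
  short-read calls cannot exclude hemizygosity or an overlapping
  deletion);
* individuals carrying several variants in one gene (candidate compound
  heterozygotes when two are in trans — without phasing only proximity
  within one read can confirm a shared chromosome);
* lookups in small candidate panels (e.g. GWAS hits).

Known-disease-panel membership and exclusion-candidate (artifact-prone
gene) status are annotated on every record, never used to drop rows.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .filtering import FilterConfig, filter_variant
from .model import AnnotatedVariant, Cohort, CohortManifest, GenePanel, VariantKey, Zygosity

# Display names for consequence classes in report summaries, matching
# the field's tabular vocabulary.
_TYPE_NAMES = {
    "missense": "non-synonymous",
    "frameshift_indel": "frameshift",
    "inframe_indel": "in-frame indel",
    "stop_gained": "stop gain",
    "start_lost": "start loss",
    "essential_splice_site": "essential splice site",
    "transcript_ablation": "transcript ablation",
    "splice_region": "splice region",
}


def _type_summary(variants: list[AnnotatedVariant]) -> str:
    counts: dict[str, int] = defaultdict(int)
    for v in variants:
        counts[_TYPE_NAMES.get(v.consequence.value, v.consequence.value)] += 1
    parts = [f"{n} {t}" for t, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return ", ".join(parts)


def _flags(gene: str, deafness_panel: GenePanel | None,
           exclusion_panel: GenePanel | None) -> tuple[bool, bool]:
    deaf = deafness_panel is not None and gene in deafness_panel
    excl = exclusion_panel is not None and gene in exclusion_panel
    return deaf, excl


@dataclass
class SharedGeneRecord:
    """A gene hit by passing variants in every member of a subgroup."""

    gene: str
    subgroup: str
    n_distinct_variants: int
    variant_type_summary: str
    exclusion_flag: bool
    deafness_flag: bool
    per_carrier_variants: dict[str, int] = field(default_factory=dict)


@dataclass
class RecurrentGeneRecord:
    gene: str
    n_individuals: int
    sample_ids: tuple[str, ...]
    deafness_flag: bool
    exclusion_flag: bool


@dataclass
class MultiHitRecord:
    """One individual with several passing variants in one gene."""

    sample_id: str
    gene: str
    n_variants: int
    zygosities: tuple[str, ...]
    same_chromosome_evidence: str  # unknown | confirmed | refuted


@dataclass
class HomozygousRecord:
    sample_id: str
    variant: AnnotatedVariant
    gene: str
    note: str = "apparently homozygous (hemizygosity or overlapping deletion not excluded)"


@dataclass
class CandidateHit:
    gene: str
    variant: AnnotatedVariant
    sample_ids: tuple[str, ...]
    zygosities: tuple[str, ...]


def _passing(cohort: Cohort, cfg: FilterConfig) -> list[AnnotatedVariant]:
    return [v for v in cohort.variants if filter_variant(v, cfg).passed]


def shared_mutated_genes(
    cohort: Cohort,
    manifest: CohortManifest,
    subgroup: str,
    cfg: FilterConfig,
    deafness_panel: GenePanel | None = None,
    exclusion_panel: GenePanel | None = None,
) -> list[SharedGeneRecord]:
    """Genes with a passing variant in every member of ``subgroup``.

    Records carry the number of distinct variants observed in the gene
    across the subgroup, a per-carrier breakdown, and a consequence-type
    summary. Sorted by gene symbol.
    """
    members = manifest.members(subgroup)
    member_set = set(members)
    by_gene_samples: dict[str, set[str]] = defaultdict(set)
    by_gene_variants: dict[str, list[AnnotatedVariant]] = defaultdict(list)
    for v in _passing(cohort, cfg):
        if not v.gene:
            continue
        carriers = member_set.intersection(v.carriers)
        if carriers:
            by_gene_samples[v.gene] |= carriers
            by_gene_variants[v.gene].append(v)
    records = []
    for gene in sorted(by_gene_samples):
        if by_gene_samples[gene] != member_set:
            continue
        variants = by_gene_variants[gene]
        distinct = {v.key for v in variants}
        per_carrier = {
            s: sum(1 for v in variants if v.zygosity_of(s).is_carrier)
            for s in members
        }
        deaf, excl = _flags(gene, deafness_panel, exclusion_panel)
        records.append(SharedGeneRecord(
            gene=gene, subgroup=subgroup, n_distinct_variants=len(distinct),
            variant_type_summary=_type_summary(
                sorted(variants, key=lambda v: v.key)),
            exclusion_flag=excl, deafness_flag=deaf,
            per_carrier_variants=per_carrier,
        ))
    return records


def recurrent_genes(
    cohort: Cohort,
    cfg: FilterConfig,
    min_individuals: int = 2,
    deafness_panel: GenePanel | None = None,
    exclusion_panel: GenePanel | None = None,
) -> list[RecurrentGeneRecord]:
    """Genes with passing variants in >= ``min_individuals`` distinct samples.

    Any zygosity counts. Sorted by descending carrier count, then gene
    symbol, for reproducible reports.
    """
    by_gene: dict[str, set[str]] = defaultdict(set)
    for v in _passing(cohort, cfg):
        if v.gene:
            by_gene[v.gene].update(v.carriers)
    records = []
    for gene, samples in by_gene.items():
        if len(samples) >= min_individuals:
            deaf, excl = _flags(gene, deafness_panel, exclusion_panel)
            records.append(RecurrentGeneRecord(
                gene=gene, n_individuals=len(samples),
                sample_ids=tuple(sorted(samples)),
                deafness_flag=deaf, exclusion_flag=excl,
            ))
    records.sort(key=lambda r: (-r.n_individuals, r.gene))
    return records


def recurrent_identical_variants(
    cohort: Cohort,
    cfg: FilterConfig,
    min_individuals: int = 2,
) -> list[tuple[AnnotatedVariant, tuple[str, ...]]]:
    """Exact (chrom, pos, ref, alt) matches carried by several samples.

    Different alternate alleles at the same position are never merged.
    """
    by_key: dict[VariantKey, tuple[AnnotatedVariant, set[str]]] = {}
    for v in _passing(cohort, cfg):
        if v.key in by_key:
            by_key[v.key][1].update(v.carriers)
        else:
            by_key[v.key] = (v, set(v.carriers))
    out = [
        (v, tuple(sorted(samples)))
        for v, samples in by_key.values()
        if len(samples) >= min_individuals
    ]
    out.sort(key=lambda item: item[0].key)
    return out


def homozygous_rare(cohort: Cohort, cfg: FilterConfig) -> list[HomozygousRecord]:
    """Passing variants called homozygous for the alternate allele.

    Reported per (sample, variant), sorted; use
    :func:`multi_person_homozygous_genes` for genes homozygous in more
    than one person.
    """
    records = []
    for v in _passing(cohort, cfg):
        for s, z in v.genotypes.items():
            if z == Zygosity.HOMOZYGOUS_ALT:
                records.append(HomozygousRecord(sample_id=s, variant=v, gene=v.gene))
    records.sort(key=lambda r: (r.sample_id, r.variant.key))
    return records


def multi_person_homozygous_genes(records: list[HomozygousRecord]) -> dict[str, list[str]]:
    """Genes apparently homozygous in two or more distinct individuals."""
    by_gene: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.gene:
            by_gene[r.gene].add(r.sample_id)
    return {g: sorted(s) for g, s in sorted(by_gene.items()) if len(s) >= 2}


def multi_hit_genes(
    cohort: Cohort,
    cfg: FilterConfig,
    min_variants: int = 2,
    read_window: int = 100,
    phase_annotations: dict[tuple[str, str], str] | None = None,
) -> list[MultiHitRecord]:
    """Individuals with >= ``min_variants`` passing variants in one gene.

    ``same_chromosome_evidence`` is "confirmed" only when at least two of
    the variants lie within ``read_window`` bp (close enough to share a
    sequencing read) *and* a phase annotation for (sample, gene) says
    "cis"; "refuted" when the annotation says "trans"; otherwise
    "unknown" — without relatives, phase generally cannot be resolved.
    """
    by_pair: dict[tuple[str, str], list[AnnotatedVariant]] = defaultdict(list)
    for v in _passing(cohort, cfg):
        if not v.gene:
            continue
        for s in v.carriers:
            by_pair[(s, v.gene)].append(v)
    records = []
    for (sample, gene), variants in by_pair.items():
        distinct = {v.key: v for v in variants}
        if len(distinct) < min_variants:
            continue
        vs = sorted(distinct.values(), key=lambda v: v.key)
        positions = sorted(v.pos for v in vs)
        within_read = any(
            b - a <= read_window for a, b in zip(positions, positions[1:])
        )
        phase = (phase_annotations or {}).get((sample, gene))
        if phase == "trans":
            evidence = "refuted"
        elif phase == "cis" and within_read:
            evidence = "confirmed"
        else:
            evidence = "unknown"
        records.append(MultiHitRecord(
            sample_id=sample, gene=gene, n_variants=len(vs),
            zygosities=tuple(v.zygosity_of(sample).value for v in vs),
            same_chromosome_evidence=evidence,
        ))
    records.sort(key=lambda r: (-r.n_variants, r.sample_id, r.gene))
    return records


def candidate_lookup(
    cohort: Cohort,
    cfg: FilterConfig,
    candidate_genes: GenePanel,
) -> list[CandidateHit]:
    """All passing variants in a small candidate panel, with carriers.

    A variant shared by several samples yields a single row listing all
    its carriers.
    """
    if len(candidate_genes) == 0:
        raise ValueError("candidate panel is empty")
    by_key: dict[VariantKey, tuple[AnnotatedVariant, set[str]]] = {}
    for v in _passing(cohort, cfg):
        if v.gene and v.gene in candidate_genes:
            if v.key in by_key:
                by_key[v.key][1].update(v.carriers)
            else:
                by_key[v.key] = (v, set(v.carriers))
    hits = []
    for v, samples in by_key.values():
        if not samples:
            continue
        ordered = tuple(sorted(samples))
        hits.append(CandidateHit(
            gene=v.gene, variant=v, sample_ids=ordered,
            zygosities=tuple(v.zygosity_of(s).value for s in ordered),
        ))
    hits.sort(key=lambda h: (h.gene, h.variant.key))
    return hits
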