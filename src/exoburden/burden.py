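"""Per-individual gene-panel burden: how many curated disease genes carry
predicted pathogenic variants in each person.

The burden of an individual is the number of *distinct* panel genes in
which they carry at least one variant passing the active filter
configuration. Zygosity is ignored (het and hom both count): this is a
dominant-model screen of gene hits, not a recessive genotype test.
Exclusion-candidate (artifact-prone) genes contribute by default and are
merely flagged; a switch recomputes without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .filtering import FilterConfig, filter_variant
from .model import Cohort, GenePanel


@dataclass
class BurdenDistribution:
    """Cohort-level distribution of per-individual panel-gene burdens."""

    panel_name: str
    tier: str
    maf_threshold: float
    per_individual: dict[str, int]
    histogram: dict[int, int]
    carrier_count: int

    @property
    def cohort_size(self) -> int:
        return len(self.per_individual)


@dataclass
class DominantCarrierSummary:
    """Counts of individuals hit in a dominant-acting gene subset."""

    n_cohort: int
    n_with_any_pathogenic: int
    n_with_lof: int

    def __post_init__(self) -> None:
        if not self.n_with_lof <= self.n_with_any_pathogenic <= self.n_cohort:
            raise ValueError("carrier counts must nest: lof <= any <= cohort")


def genes_hit(
    sample_id: str,
    cohort: Cohort,
    panel: GenePanel,
    cfg: FilterConfig,
    exclusion_panel: GenePanel | None = None,
    drop_exclusion_candidates: bool = False,
) -> set[str]:
    """Distinct panel genes in which ``sample_id`` carries a passing variant.

    Exclusion-candidate genes are included by default (they are flagged
    downstream, not removed); pass ``drop_exclusion_candidates=True`` to
    recompute without them.
    """
    if sample_id not in cohort.samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    hit: set[str] = set()
    for v in cohort.variants:
        if not v.gene or v.gene not in panel:
            continue
        if drop_exclusion_candidates and exclusion_panel and v.gene in exclusion_panel:
            continue
        if not v.zygosity_of(sample_id).is_carrier:
            continue
        if filter_variant(v, cfg).passed:
            hit.add(v.gene)
    return hit


def burden_distribution(
    cohort: Cohort,
    panel: GenePanel,
    cfg: FilterConfig,
    exclusion_panel: GenePanel | None = None,
    drop_exclusion_candidates: bool = False,
) -> BurdenDistribution:
    """Per-individual burden counts and their histogram over the cohort."""
    if not cohort.samples:
        raise ValueError("cohort has no samples")
    per_individual = {
        s: len(genes_hit(s, cohort, panel, cfg, exclusion_panel,
                         drop_exclusion_candidates))
        for s in cohort.samples
    }
    histogram: dict[int, int] = {}
    for n in per_individual.values():
        histogram[n] = histogram.get(n, 0) + 1
    carrier_count = sum(1 for n in per_individual.values() if n > 0)
    return BurdenDistribution(
        panel_name=panel.name,
        tier=cfg.vote_mode,
        maf_threshold=cfg.maf_threshold,
        per_individual=per_individual,
        histogram=dict(sorted(histogram.items())),
        carrier_count=carrier_count,
    )


def dominant_carrier_summary(
    cohort: Cohort,
    dominant_genes: GenePanel | frozenset[str] | set[str],
    cfg: FilterConfig,
) -> DominantCarrierSummary:
    """How many individuals carry pathogenic / LoF hits in dominant genes.

    Counts individuals with at least one passing variant at the
    configured tier, and with at least one passing LoF variant, in genes
    where a single damaging allele is expected to act.
    """
    if isinstance(dominant_genes, GenePanel):
        genes = dominant_genes.dominant_subset or dominant_genes.genes
    else:
        genes = frozenset(g.upper() for g in dominant_genes)
    lof_cfg = cfg.replace(vote_mode="lof_only")
    any_hit: set[str] = set()
    lof_hit: set[str] = set()
    for v in cohort.variants:
        if v.gene not in genes:
            continue
        carriers = v.carriers
        if not carriers:
            continue
        if filter_variant(v, cfg).passed:
            any_hit.update(carriers)
        if filter_variant(v, lof_cfg).passed:
            lof_hit.update(carriers)
    return DominantCarrierSummary(
        n_cohort=len(cohort.samples),
        n_with_any_pathogenic=len(any_hit),
        n_with_lof=len(lof_hit),
    )


@dataclass(frozen=True)
class DistributionComparison:
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    u_statistic: float
    effect_size: float  # |common-language effect - 0.5|, symmetric in a/b
    pvalue: float


def compare_distributions(a: BurdenDistribution, b: BurdenDistribution) -> DistributionComparison:
    """Compare two burden distributions with a two-sample rank test.

    Uses the Mann-Whitney U test (two-sided) on the per-individual
    counts. The reported effect size |U/(n_a n_b) - 1/2| and the p-value
    are symmetric under swapping the inputs.
    """
    xs = np.array(list(a.per_individual.values()), dtype=float)
    ys = np.array(list(b.per_individual.values()), dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("cannot compare empty burden distributions")
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided")
    effect = abs(res.statistic / (xs.size * ys.size) - 0.5)
    return DistributionComparison(
        mean_a=float(xs.mean()),
        mean_b=float(ys.mean()),
        median_a=float(np.median(xs)),
        median_b=float(np.median(ys)),
        u_statistic=float(res.statistic),
        effect_size=float(effect),
        pvalue=float(min(1.0, res.pvalue)),
    )


def burden_grid(
    cohort: Cohort,
    panels: dict[str, GenePanel],
    maf_thresholds=(0.10, 0.01),
    vote_modes=("majority", "all", "lof_only"),
    base_cfg: FilterConfig | None = None,
    exclusion_panel: GenePanel | None = None,
) -> list[BurdenDistribution]:
    """The full burden grid: panels x MAF tiers x pathogenicity tiers."""
    base = base_cfg or FilterConfig()
    out = []
    for name, panel in panels.items():
        for thr in maf_thresholds:
            for mode in vote_modes:
                cfg = base.replace(maf_threshold=thr, vote_mode=mode)
                out.append(burden_distribution(cohort, panel, cfg, exclusion_panel))
    return out
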