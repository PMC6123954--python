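"""The variant prioritization cascade.

Variants pass through four stages in order:

1. **quality gate** — phred site quality >= 30, read depth >= 20, mapping
   quality >= 45 (defaults; the gate can be disabled wholesale for
   pre-validated call sets such as public reference panels);
2. **rarity gate** — the minor allele frequency in a primary reference
   population (with a fallback population when the primary has no record,
   and "novel" = 0 when neither does) is compared against a tier
   threshold (10%, 1%, 0.5% or 0.05% in the study design);
3. **consequence gate** — only protein-altering classes are retained
   (LoF classes plus missense, in-frame indel, splice region by default);
4. **pathogenicity tier** — LoF variants count as pathogenic outright;
   other variants are voted on by in-silico predictors, either by
   majority or unanimously depending on the tier.

A cross-population flag marks variants that are rare in the primary
population but common (>10% by default) elsewhere; it is informational
and never filters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .model import (
    LOF_CONSEQUENCES,
    AnnotatedVariant,
    Consequence,
    Verdict,
)

VOTE_MODES = ("majority", "all", "lof_only")

#: Consequence classes retained by default: LoF plus protein-altering.
DEFAULT_RETAINED_CONSEQUENCES = frozenset(LOF_CONSEQUENCES) | {
    Consequence.MISSENSE,
    Consequence.INFRAME_INDEL,
    Consequence.SPLICE_REGION,
}


@dataclass(frozen=True)
class FilterConfig:
    """All thresholds and switches of the cascade.

    ``maf_inclusive`` selects the comparator of the rarity gate: the
    low-stringency tiers use <= ("MAF of 10% or lower") while the
    very-rare tiers use strict < ("MAF of < 0.5%").
    """

    min_site_quality: float = 30.0
    min_depth: int = 20
    min_mapping_quality: float = 45.0
    quality_gate_enabled: bool = True
    maf_threshold: float = 0.10
    maf_inclusive: bool = True
    primary_population: str = "NFE"
    fallback_population: str = "EUR_1KG"
    retained_consequences: frozenset[Consequence] = DEFAULT_RETAINED_CONSEQUENCES
    vote_mode: str = "majority"
    cross_population_flag_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.vote_mode not in VOTE_MODES:
            raise ValueError(f"vote_mode must be one of {VOTE_MODES}")
        if not 0.0 < self.maf_threshold <= 1.0:
            raise ValueError("maf_threshold must be in (0, 1]")
        for name in ("min_site_quality", "min_depth", "min_mapping_quality",
                     "cross_population_flag_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def replace(self, **kw) -> "FilterConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["retained_consequences"] = sorted(c.value for c in self.retained_consequences)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        if "retained_consequences" in d:
            d["retained_consequences"] = frozenset(
                Consequence(c) for c in d["retained_consequences"]
            )
        return cls(**d)


# Named presets for the study's two analyses plus the strict dominant
# screen: common variants (<=10%), very rare (<0.5%, the recommended
# recessive hearing-loss filter and the pipeline default for discovery),
# and dominant-strict (<0.05%, the recommended dominant filter).
PRESETS: dict[str, FilterConfig] = {
    "common": FilterConfig(maf_threshold=0.10, maf_inclusive=True),
    "very_rare": FilterConfig(maf_threshold=0.005, maf_inclusive=False),
    "dominant_strict": FilterConfig(maf_threshold=0.0005, maf_inclusive=False),
}


def preset(name: str, **overrides) -> FilterConfig:
    """Return a named preset, optionally with field overrides."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return cfg.replace(**overrides) if overrides else cfg


@dataclass(frozen=True)
class FilterOutcome:
    """Full record of one variant's passage through the cascade.

    ``failed_stages`` lists every failing stage (not just the first) in
    pipeline order; ``passed`` is true iff it is empty.
    """

    passed: bool
    failed_stages: tuple[str, ...]
    effective_maf: float
    maf_source: str
    tier_pass: dict[str, bool]
    cross_population_common: bool


def quality_gate(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Site-level call quality gate; always passes when disabled.

    Missing metrics fail the gate when it is enabled (conservative:
    an unverifiable call is not promoted).
    """
    if not cfg.quality_gate_enabled:
        return True
    if v.site_quality is None or v.read_depth is None or v.mapping_quality is None:
        return False
    return (
        v.site_quality >= cfg.min_site_quality
        and v.read_depth >= cfg.min_depth
        and v.mapping_quality >= cfg.min_mapping_quality
    )


def _quality_stage_label(v: AnnotatedVariant, cfg: FilterConfig) -> str | None:
    if not cfg.quality_gate_enabled:
        return None
    if v.site_quality is None or v.read_depth is None or v.mapping_quality is None:
        return "quality:missing"
    if quality_gate(v, cfg):
        return None
    return "quality"


def resolve_maf(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[float, str]:
    """Effective MAF with its source.

    Primary-population frequency when recorded; otherwise the fallback
    population; otherwise 0 with source "novel" — a variant never seen
    in a reference population is treated as maximally rare.
    """
    if cfg.primary_population in v.frequencies:
        return v.frequencies[cfg.primary_population], "primary"
    if cfg.fallback_population in v.frequencies:
        return v.frequencies[cfg.fallback_population], "fallback"
    return 0.0, "novel"


def maf_gate(effective_maf: float, cfg: FilterConfig) -> bool:
    if cfg.maf_inclusive:
        return effective_maf <= cfg.maf_threshold
    return effective_maf < cfg.maf_threshold


def flag_cross_population(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True when any non-primary population is common for this allele.

    Informational only: a variant rare in the primary reference
    population but at, say, 60% elsewhere is retained yet flagged.
    """
    thr = cfg.cross_population_flag_threshold
    return any(
        maf > thr
        for pop, maf in v.frequencies.items()
        if pop != cfg.primary_population
    )


def consequence_gate(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return v.consequence in cfg.retained_consequences


def pathogenicity_tiers(v: AnnotatedVariant) -> dict[str, bool]:
    """Evaluate the three pathogenicity tiers for one variant.

    LoF consequences pass every tier outright. For other variants the
    predictor verdicts vote, with "unknown" verdicts excluded from the
    denominator: "majority" needs strictly more than half of the
    non-unknown verdicts deleterious, "all" needs every non-unknown
    verdict deleterious (and at least one such verdict). A non-LoF
    variant with no usable verdicts fails both voting tiers.

    Tier nesting holds by construction: lof_only => all => majority.
    """
    lof = v.consequence.is_lof
    informative = [c for c in v.predictor_calls if c.verdict != Verdict.UNKNOWN]
    n_del = sum(1 for c in informative if c.verdict == Verdict.DELETERIOUS)
    tier_all = lof or (len(informative) > 0 and n_del == len(informative))
    tier_majority = lof or (len(informative) > 0 and n_del * 2 > len(informative))
    return {"majority": tier_majority, "all": tier_all, "lof_only": lof}


def filter_variant(v: AnnotatedVariant, cfg: FilterConfig) -> FilterOutcome:
    """Run the full cascade on one variant.

    Every stage is evaluated (so ``failed_stages`` is complete, which the
    per-stage audit relies on), and the variant passes iff all gates pass
    and it reaches the configured pathogenicity tier.
    """
    failed: list[str] = []

    qlabel = _quality_stage_label(v, cfg)
    if qlabel is not None:
        failed.append(qlabel)

    eff_maf, source = resolve_maf(v, cfg)
    if not maf_gate(eff_maf, cfg):
        failed.append("maf")

    if not consequence_gate(v, cfg):
        failed.append("consequence")

    tiers = pathogenicity_tiers(v)
    if not tiers[cfg.vote_mode]:
        failed.append("tier")

    return FilterOutcome(
        passed=not failed,
        failed_stages=tuple(failed),
        effective_maf=eff_maf,
        maf_source=source,
        tier_pass=tiers,
        cross_population_common=flag_cross_population(v, cfg),
    )


def passing_variants(cohort, cfg: FilterConfig):
    """All cohort variants passing the cascade under ``cfg``."""
    return [v for v in cohort.variants if filter_variant(v, cfg).passed]
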