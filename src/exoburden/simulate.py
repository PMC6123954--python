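"""Synthetic annotated-cohort generator.

Emulates a multi-subgroup exome cohort with the statistical structure the
downstream analyses assume: a realistic (log-uniform) allele-frequency
spectrum, partially concordant in-silico predictor verdicts, genotype
zygosity, artifact-prone genes with inflated hit rates, and *planted*
facts — subgroup-shared causal genes, recurrent identical variants,
homozygotes, and a multi-variant gene in one individual — recorded in a
:class:`TruthTable` that serves as the oracle for every recovery test.

Genes live on synthetic contigs (one contig per gene, gene = interval),
so no genome build is needed and coordinates are internally consistent.
Planted features are injected after background generation, leaving
background statistics unperturbed away from planted loci. Identical
seeds yield byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import write_cohort_vcf, write_manifest, write_sidecar
from .model import (
    AnnotatedVariant,
    Cohort,
    CohortManifest,
    Consequence,
    GenePanel,
    PredictorCall,
    Verdict,
    Zygosity,
)

CONTIG_LENGTH = 100_000

# Gene symbols printed in the source study's main-text tables, used to
# seed the synthetic panels so worked examples read naturally. The
# remainder of each panel is filled with clearly synthetic symbols.
DEAFNESS_SEED_GENES = [
    "GJB2", "MYO6", "HOMER2", "WFS1", "GPR98", "PAX2", "TECTA", "LRIG3",
    "LAMA2", "CDH23", "DMD", "DUOX2", "RBPJ", "USH2A", "COL11A1", "NAV2",
    "CPXM2", "COL4A4", "LRP2", "MYO15A", "MYH9", "TSPEAR", "PCDH15",
    "OTOG", "MECOM", "NTN1", "TCOF1", "COL11A2", "CELSR1", "SLC9A3R1",
    "COL9A1", "TJP2", "ALMS1", "JAG1", "ATP2B2", "SLC26A4", "LRIG1",
    "LOXHD1", "CHRNA9", "RDX", "CHD7", "NTF3", "ELMOD3", "SLC4A7",
    "ATP8B1", "NPC1", "KARS", "ERCC6", "WBP2", "MIR96", "KCNQ1", "OTOF",
]
DOMINANT_SEED_GENES = [
    "MYO6", "HOMER2", "WFS1", "MYH9", "COL11A2", "TECTA", "TJP2",
]
RETINAL_SEED_GENES = ["RHO", "RPGR", "ABCA4", "USH2A", "RPE65", "CRB1", "PRPH2"]
EXCLUSION_SEED_GENES = [
    "TTN", "SIRPA", "MUC4", "MUC16", "OBSCN", "HYDIN", "PDE4DIP", "AHNAK2",
]
GWAS_CANDIDATE_GENES = [
    "PCDH20", "GRM7", "ESRRG", "SIK3", "SLC28A3", "TRIOBP", "ISG20", "ACAN",
]
BACKGROUND_SEED_GENES = [
    "NEDD4", "ZAN", "MON1B", "NEFH", "DNAH2", "LRBA", "ADC", "CHD3",
    "DNAH3", "MACF1", "PTGER4", "UBE2O", "LPP",
]

_LOF_LABELS = [
    Consequence.TRANSCRIPT_ABLATION,
    Consequence.ESSENTIAL_SPLICE_SITE,
    Consequence.FRAMESHIFT_INDEL,
    Consequence.STOP_GAINED,
    Consequence.START_LOST,
]
_LOF_WEIGHTS = [0.05, 0.20, 0.35, 0.30, 0.10]
_BASES = ["A", "C", "G", "T"]


@dataclass(frozen=True)
class PanelSpec:
    """Sizes of the curated panels the generator emits.

    Defaults mirror the study's curated lists: 357 deafness genes with a
    dominant-acting subset of 33, 265 retinal disease genes, 507
    platform-artifact exclusion candidates and 8 GWAS candidate genes.
    ``exclusion_overlap`` deafness genes are also placed on the exclusion
    list (disease and artifact lists genuinely overlap).
    """

    deafness: int = 357
    dominant: int = 33
    retinal: int = 265
    exclusion: int = 507
    gwas: int = 8
    exclusion_overlap: int = 2

    def __post_init__(self) -> None:
        for name in ("deafness", "dominant", "retinal", "exclusion", "gwas"):
            if getattr(self, name) < 0:
                raise ValueError(f"panel size {name} must be >= 0")
        if self.dominant > self.deafness:
            raise ValueError("dominant subset cannot exceed deafness panel size")
        if self.exclusion_overlap > min(self.deafness, self.exclusion):
            raise ValueError("exclusion_overlap larger than the panels")


def _fill(seeds: list[str], size: int, prefix: str) -> list[str]:
    out = list(seeds[:size])
    i = 1
    while len(out) < size:
        out.append(f"{prefix}{i:04d}")
        i += 1
    return out


def panel_symbol_lists(spec: PanelSpec = PanelSpec()) -> dict[str, list[str]]:
    """Deterministic ordered symbol lists for each panel."""
    deafness = _fill(DEAFNESS_SEED_GENES, spec.deafness, "SYNDFN")
    dom_seeds = [g for g in DOMINANT_SEED_GENES if g in deafness]
    dominant = dom_seeds + [g for g in deafness if g not in dom_seeds]
    dominant = dominant[: spec.dominant]
    retinal = _fill(RETINAL_SEED_GENES, spec.retinal, "SYNRET")
    overlap = [g for g in deafness if g.startswith("SYNDFN")][: spec.exclusion_overlap]
    exclusion = _fill(EXCLUSION_SEED_GENES + overlap, spec.exclusion, "SYNEXC")
    gwas = _fill(GWAS_CANDIDATE_GENES, spec.gwas, "SYNGWA")
    return {
        "deafness": deafness,
        "dominant": dominant,
        "retinal": retinal,
        "exclusion": exclusion,
        "gwas": gwas,
    }


def generate_gene_panels(spec: PanelSpec = PanelSpec()) -> dict[str, GenePanel]:
    """Build the curated panels (deterministic, no randomness)."""
    lists = panel_symbol_lists(spec)
    return {
        "deafness": GenePanel.from_symbols(
            "deafness", lists["deafness"], lists["dominant"]),
        "retinal": GenePanel.from_symbols("retinal", lists["retinal"]),
        "exclusion": GenePanel.from_symbols(
            "exclusion", lists["exclusion"], is_exclusion_list=True),
        "gwas": GenePanel.from_symbols("gwas", lists["gwas"]),
    }


def _default_subgroups() -> dict[str, int]:
    return {"Dominant": 10, "Recessive": 10, "Metabolic": 5, "Sensory": 5}


def _default_shared() -> dict[str, str]:
    return {
        "Dominant": "DNAH2",
        "Recessive": "TTN",
        "Metabolic": "MON1B",
        "Sensory": "NEDD4",
    }


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study design: a 30-sample cohort split
    10/10/5/5 across Dominant/Recessive/Metabolic/Sensory subgroups,
    curated panels at the study's printed sizes, a log-uniform MAF
    spectrum, six partially concordant predictors, one shared causal
    gene planted per subgroup, five recurrent identical very rare
    variants, three very rare homozygotes and one five-variant gene in a
    single individual, plus a guaranteed minimum of ten deafness-panel
    genes with common-tier pathogenic hits per sample.
    """

    seed: int = 0
    subgroup_sizes: dict[str, int] = field(default_factory=_default_subgroups)
    n_background_genes: int = 400
    panel_spec: PanelSpec = field(default_factory=PanelSpec)
    per_gene_hit_prob: float = 0.01
    maf_spectrum: tuple[float, float] = (1e-5, 0.5)
    frac_missing_primary_freq: float = 0.05
    n_predictors: int = 6
    predictor_concordance: float = 0.8
    predictor_unknown_rate: float = 0.05
    lof_fraction: float = 0.10
    benign_fraction: float = 0.30
    hom_rate: float = 0.02
    low_quality_rate: float = 0.05
    cross_pop_common_rate: float = 0.02
    exclusion_inflation: float = 3.0
    min_panel_hits: int = 10
    planted_shared_genes: dict[str, str] = field(default_factory=_default_shared)
    planted_recurrent_variants: int = 5
    planted_homozygotes: int = 3
    planted_multi_hit: tuple[tuple[str, str, int], ...] = (("Dominant01", "WFS1", 5),)
    primary_population: str = "NFE"
    fallback_population: str = "EUR_1KG"
    other_population: str = "AFR"

    def __post_init__(self) -> None:
        for name in ("per_gene_hit_prob", "frac_missing_primary_freq",
                     "predictor_concordance", "predictor_unknown_rate",
                     "lof_fraction", "benign_fraction", "hom_rate",
                     "low_quality_rate", "cross_pop_common_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.maf_spectrum
        if not (0 < lo <= hi <= 1):
            raise ValueError("maf_spectrum must satisfy 0 < lo <= hi <= 1")

    def sample_ids(self) -> list[str]:
        out = []
        for label, n in self.subgroup_sizes.items():
            out.extend(f"{label}{i:02d}" for i in range(1, n + 1))
        return out


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort: the oracle for recovery tests."""

    planted_shared_genes: dict[str, str]
    planted_recurrent: list[dict]
    planted_homozygotes: list[dict]
    planted_multi_hit: list[dict]
    guaranteed_min_panel_hits: int
    panel_hits: dict[str, list[str]]
    n_background_variants: int

    def planted_keys(self) -> set[tuple]:
        """Keys of all planted variants (any kind)."""
        keys: set[tuple] = set()
        for rec in self.planted_recurrent:
            keys.add(tuple(rec["key"]))
        for rec in self.planted_homozygotes:
            keys.add(tuple(rec["key"]))
        for rec in self.planted_multi_hit:
            keys.update(tuple(k) for k in rec["keys"])
        for rec in self.planted_shared_variant_keys:
            keys.add(tuple(rec))
        return keys

    planted_shared_variant_keys: list[tuple] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulationResult:
    cohort: Cohort
    panels: dict[str, GenePanel]
    manifest: CohortManifest
    truth: TruthTable
    gene_order: list[str]


class _VariantFactory:
    """Draws variants one at a time from a single seeded stream."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.used_positions: dict[str, set[int]] = {}
        self._rsid = 1000

    def _position(self, gene: str) -> int:
        used = self.used_positions.setdefault(gene, set())
        while True:
            pos = int(self.rng.integers(1, CONTIG_LENGTH - 1000))
            if pos not in used:
                used.add(pos)
                return pos

    def _alleles(self, consequence: Consequence) -> tuple[str, str]:
        rng = self.rng
        base = _BASES[rng.integers(0, 4)]
        if consequence == Consequence.FRAMESHIFT_INDEL:
            ins = "".join(_BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 3))))
            return base, base + ins
        if consequence == Consequence.INFRAME_INDEL:
            ins = "".join(_BASES[rng.integers(0, 4)] for _ in range(3))
            return base, base + ins
        alt = _BASES[rng.integers(0, 4)]
        while alt == base:
            alt = _BASES[rng.integers(0, 4)]
        return base, alt

    def _quality(self, force_good: bool) -> tuple[float, int, float, bool]:
        rng = self.rng
        low = (not force_good) and rng.random() < self.cfg.low_quality_rate
        if low:
            which = rng.integers(0, 3)
            qual = float(rng.uniform(5, 29.5)) if which == 0 else float(rng.uniform(35, 200))
            dp = int(rng.integers(1, 20)) if which == 1 else int(rng.integers(25, 120))
            mq = float(rng.uniform(10, 44.5)) if which == 2 else float(rng.uniform(46, 60))
        else:
            qual = float(rng.uniform(35, 200))
            dp = int(rng.integers(25, 120))
            mq = float(rng.uniform(46, 60))
        return round(qual, 2), dp, round(mq, 2), low

    def _frequencies(self, maf: float) -> dict[str, float]:
        cfg, rng = self.cfg, self.rng
        freqs: dict[str, float] = {}
        if rng.random() < cfg.frac_missing_primary_freq:
            freqs[cfg.fallback_population] = maf
        else:
            freqs[cfg.primary_population] = maf
            if rng.random() < 0.5:
                alt = min(1.0, max(0.0, maf * float(rng.uniform(0.8, 1.2))))
                freqs[cfg.fallback_population] = round(alt, 8)
        if rng.random() < cfg.cross_pop_common_rate:
            freqs[cfg.other_population] = round(float(rng.uniform(0.2, 0.8)), 8)
        return freqs

    def _predictor_calls(self, latent_deleterious: bool) -> list[PredictorCall]:
        cfg, rng = self.cfg, self.rng
        agree = Verdict.DELETERIOUS if latent_deleterious else Verdict.BENIGN
        disagree = Verdict.BENIGN if latent_deleterious else Verdict.DELETERIOUS
        calls = []
        for i in range(cfg.n_predictors):
            if rng.random() < cfg.predictor_unknown_rate:
                verdict = Verdict.UNKNOWN
            elif rng.random() < cfg.predictor_concordance:
                verdict = agree
            else:
                verdict = disagree
            calls.append(PredictorCall(f"pred{i + 1}", verdict))
        return calls

    def _maybe_rsid(self) -> str | None:
        if self.rng.random() < 0.3:
            self._rsid += int(self.rng.integers(1, 5000))
            return f"rs{self._rsid}"
        return None

    def background(self, gene: str, sample: str) -> tuple[AnnotatedVariant, bool]:
        """One background variant; returns it plus a by-construction flag
        saying whether it passes the common-tier cascade (quality ok,
        MAF <= 10%, retained consequence, majority-pathogenic)."""
        cfg, rng = self.cfg, self.rng
        lo, hi = cfg.maf_spectrum
        maf = round(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))), 8)
        deleterious = rng.random() >= cfg.benign_fraction
        if deleterious and rng.random() < cfg.lof_fraction:
            idx = rng.choice(len(_LOF_LABELS), p=_LOF_WEIGHTS)
            consequence = _LOF_LABELS[idx]
            calls: list[PredictorCall] = []
        elif deleterious:
            consequence = [Consequence.MISSENSE, Consequence.INFRAME_INDEL,
                           Consequence.SPLICE_REGION][rng.choice(3, p=[0.8, 0.1, 0.1])]
            calls = self._predictor_calls(True)
        else:
            consequence = [Consequence.SYNONYMOUS, Consequence.INTRONIC,
                           Consequence.MISSENSE][rng.choice(3, p=[0.5, 0.3, 0.2])]
            calls = self._predictor_calls(False)
        qual, dp, mq, low = self._quality(force_good=False)
        ref, alt = self._alleles(consequence)
        zyg = Zygosity.HOMOZYGOUS_ALT if rng.random() < cfg.hom_rate else Zygosity.HETEROZYGOUS
        v = AnnotatedVariant(
            chrom=gene, pos=self._position(gene), ref=ref, alt=alt,
            site_quality=qual, read_depth=dp, mapping_quality=mq,
            gene=gene, consequence=consequence,
            frequencies=self._frequencies(maf), predictor_calls=calls,
            variant_id=self._maybe_rsid(), genotypes={sample: zyg},
        )
        passes_common = (not low) and maf <= 0.10 and self._passes_tier(v)
        return v, passes_common

    @staticmethod
    def _passes_tier(v: AnnotatedVariant) -> bool:
        # straight-line bookkeeping: retained consequence + majority vote
        from .model import LOF_CONSEQUENCES
        if v.consequence in LOF_CONSEQUENCES:
            return True
        if v.consequence not in (Consequence.MISSENSE, Consequence.INFRAME_INDEL,
                                 Consequence.SPLICE_REGION):
            return False
        informative = [c for c in v.predictor_calls if c.verdict != Verdict.UNKNOWN]
        n_del = sum(1 for c in informative if c.verdict == Verdict.DELETERIOUS)
        return len(informative) > 0 and n_del * 2 > len(informative)

    def planted(self, gene: str, carriers: dict[str, Zygosity],
                maf_lo: float, maf_hi: float) -> AnnotatedVariant:
        """A guaranteed-pass variant: good quality, missense with all
        predictors deleterious, MAF log-uniform in [maf_lo, maf_hi]."""
        rng = self.rng
        maf = round(float(np.exp(rng.uniform(np.log(maf_lo), np.log(maf_hi)))), 8)
        qual, dp, mq, _ = self._quality(force_good=True)
        ref, alt = self._alleles(Consequence.MISSENSE)
        calls = [PredictorCall(f"pred{i + 1}", Verdict.DELETERIOUS)
                 for i in range(self.cfg.n_predictors)]
        freqs = {self.cfg.primary_population: maf}
        return AnnotatedVariant(
            chrom=gene, pos=self._position(gene), ref=ref, alt=alt,
            site_quality=qual, read_depth=dp, mapping_quality=mq,
            gene=gene, consequence=Consequence.MISSENSE,
            frequencies=freqs, predictor_calls=calls,
            variant_id=None, genotypes=dict(carriers),
        )


def simulate_cohort(cfg: SyntheticConfig) -> SimulationResult:
    """Generate a cohort in memory, with its panels, manifest and truth."""
    rng = np.random.default_rng(cfg.seed)
    panels = generate_gene_panels(cfg.panel_spec)
    lists = panel_symbol_lists(cfg.panel_spec)

    background_genes = _fill(
        BACKGROUND_SEED_GENES, cfg.n_background_genes, "SYNBG")
    gene_order: list[str] = []
    seen: set[str] = set()
    for group in (lists["deafness"], lists["retinal"], lists["exclusion"],
                  lists["gwas"], background_genes):
        for g in group:
            if g not in seen:
                seen.add(g)
                gene_order.append(g)

    samples = cfg.sample_ids()
    manifest = CohortManifest(assignments={
        f"{label}{i:02d}": label
        for label, n in cfg.subgroup_sizes.items()
        for i in range(1, n + 1)
    })

    _validate_planted(cfg, seen, samples)

    factory = _VariantFactory(cfg, rng)
    exclusion_genes = panels["exclusion"].genes
    p = np.full(len(gene_order), cfg.per_gene_hit_prob)
    for j, g in enumerate(gene_order):
        if g in exclusion_genes:
            p[j] = min(1.0, cfg.per_gene_hit_prob * cfg.exclusion_inflation)

    variants: list[AnnotatedVariant] = []
    deafness_genes = panels["deafness"].genes
    common_pass_genes: dict[str, set[str]] = {s: set() for s in samples}

    hits = rng.random((len(samples), len(gene_order))) < p[None, :]
    for i, sample in enumerate(samples):
        for j in np.nonzero(hits[i])[0]:
            gene = gene_order[j]
            v, passes_common = factory.background(gene, sample)
            variants.append(v)
            if passes_common and gene in deafness_genes:
                common_pass_genes[sample].add(gene)
    n_background = len(variants)

    # top up: guarantee a minimum number of deafness-panel genes with
    # common-tier pathogenic hits for every sample
    target = min(cfg.min_panel_hits, len(deafness_genes))
    deafness_sorted = sorted(deafness_genes)
    for sample in samples:
        have = common_pass_genes[sample]
        candidates = [g for g in deafness_sorted if g not in have]
        while len(have) < target and candidates:
            idx = int(rng.integers(0, len(candidates)))
            gene = candidates.pop(idx)
            v = factory.planted(gene, {sample: Zygosity.HETEROZYGOUS},
                                1e-4, 0.05)
            variants.append(v)
            have.add(gene)

    truth = TruthTable(
        planted_shared_genes=dict(cfg.planted_shared_genes),
        planted_recurrent=[],
        planted_homozygotes=[],
        planted_multi_hit=[],
        guaranteed_min_panel_hits=target,
        panel_hits={s: sorted(g) for s, g in common_pass_genes.items()},
        n_background_variants=n_background,
    )

    # shared causal genes: one distinct common-tier variant per member,
    # MAF in [2%, 9%] so these facts belong to the common tier only
    for subgroup, gene in cfg.planted_shared_genes.items():
        for member in manifest.members(subgroup):
            v = factory.planted(gene, {member: Zygosity.HETEROZYGOUS},
                                0.02, 0.09)
            variants.append(v)
            truth.planted_shared_variant_keys.append(list(v.key))

    # recurrent identical very rare variants shared by 2-3 samples
    shared_gene_values = set(cfg.planted_shared_genes.values())
    recurrent_pool = [g for g in background_genes
                      if g not in shared_gene_values][: max(1, len(background_genes))]
    for _ in range(cfg.planted_recurrent_variants):
        gene = recurrent_pool[int(rng.integers(0, len(recurrent_pool)))]
        m = int(rng.integers(2, 4))
        chosen = list(rng.choice(len(samples), size=m, replace=False))
        carriers = {samples[k]: Zygosity.HETEROZYGOUS for k in sorted(chosen)}
        v = factory.planted(gene, carriers, 1e-5, 0.004)
        variants.append(v)
        truth.planted_recurrent.append({
            "key": list(v.key), "gene": gene,
            "samples": sorted(carriers),
        })

    # very rare homozygotes
    for _ in range(cfg.planted_homozygotes):
        gene = recurrent_pool[int(rng.integers(0, len(recurrent_pool)))]
        sample = samples[int(rng.integers(0, len(samples)))]
        v = factory.planted(gene, {sample: Zygosity.HOMOZYGOUS_ALT}, 1e-5, 0.004)
        variants.append(v)
        truth.planted_homozygotes.append({
            "key": list(v.key), "gene": gene, "sample": sample,
        })

    # multi-hit: several very rare variants in one gene of one individual
    for sample, gene, n_var in cfg.planted_multi_hit:
        keys = []
        for _ in range(n_var):
            v = factory.planted(gene, {sample: Zygosity.HETEROZYGOUS},
                                1e-5, 0.004)
            variants.append(v)
            keys.append(list(v.key))
        truth.planted_multi_hit.append({
            "sample": sample, "gene": gene, "n_variants": n_var, "keys": keys,
        })

    order = {g: i for i, g in enumerate(gene_order)}
    variants.sort(key=lambda v: (order[v.chrom], v.pos, v.ref, v.alt))
    cohort = Cohort(samples=samples, variants=variants)
    return SimulationResult(cohort=cohort, panels=panels, manifest=manifest,
                            truth=truth, gene_order=gene_order)


def _validate_planted(cfg: SyntheticConfig, universe: set[str],
                      samples: list[str]) -> None:
    for subgroup, gene in cfg.planted_shared_genes.items():
        if subgroup not in cfg.subgroup_sizes:
            raise ValueError(f"planted shared gene for unknown subgroup {subgroup!r}")
        if gene not in universe:
            raise ValueError(f"planted gene {gene!r} outside the gene universe")
    for sample, gene, n_var in cfg.planted_multi_hit:
        if sample not in samples:
            raise ValueError(f"planted multi-hit sample {sample!r} not in cohort")
        if gene not in universe:
            raise ValueError(f"planted gene {gene!r} outside the gene universe")
        if n_var < 2:
            raise ValueError("multi-hit plants need n_variants >= 2")


def generate_cohort(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write all its files to ``outdir``.

    Emits an uncompressed VCF with inline annotations, a sidecar
    annotation TSV, the cohort manifest, one text file per gene panel
    and the truth table as JSON. Deterministic under the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(cfg)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "sidecar": outdir / "annotations.tsv",
        "manifest": outdir / "manifest.tsv",
        "truth": outdir / "truth.json",
    }
    contigs = {g: CONTIG_LENGTH for g in sim.gene_order}
    write_cohort_vcf(sim.cohort, paths["vcf"], contig_lengths=contigs)
    write_sidecar(sim.cohort, paths["sidecar"])
    write_manifest(sim.manifest, paths["manifest"])
    sim.truth.to_json(paths["truth"])
    lists = panel_symbol_lists(cfg.panel_spec)
    panel_files = {
        "deafness_panel": ("deafness_genes.txt", lists["deafness"]),
        "dominant_panel": ("dominant_deafness_genes.txt", lists["dominant"]),
        "retinal_panel": ("retinal_genes.txt", lists["retinal"]),
        "exclusion_panel": ("exclusion_candidates.txt", lists["exclusion"]),
        "gwas_panel": ("gwas_candidate_genes.txt", lists["gwas"]),
    }
    for key, (fname, symbols) in panel_files.items():
        path = outdir / fname
        path.write_text("\n".join(symbols) + "\n" if symbols else "")
        paths[key] = path
    return paths
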