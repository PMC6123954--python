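"""End-to-end orchestration: filter -> burden -> discovery, with a
per-stage audit ledger.

``run_pipeline`` reads a cohort, manifest and panels from files, runs the
analyses requested for each configured preset and writes a report bundle
plus an audit JSON recording, for every sample, how many carried
variants survive each stage of the cascade (total -> quality -> MAF ->
consequence -> tier) together with cohort means. The audit counts are
cumulative survival counts, hence monotone non-increasing along the
stage order.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import discovery
from .burden import burden_grid, dominant_carrier_summary
from .filtering import FilterConfig, filter_variant, preset
from .io_formats import (
    read_cohort_vcf,
    read_gene_panel,
    read_manifest,
    write_report,
)
from .model import Cohort, CohortManifest, GenePanel

STAGES = ("total", "quality", "maf", "consequence", "tier")


@dataclass
class RunConfig:
    """Inputs and switches of one pipeline run."""

    vcf: str
    manifest: str
    outdir: str
    sidecar: str | None = None
    annotation_source: str = "inline"
    deafness_panel: str | None = None
    dominant_panel: str | None = None
    retinal_panel: str | None = None
    exclusion_panel: str | None = None
    gwas_panel: str | None = None
    presets: tuple[str, ...] = ("common", "very_rare")
    preset_overrides: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "presets" in raw:
            raw["presets"] = tuple(raw["presets"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("vcf", "manifest", "sidecar", "deafness_panel",
                     "dominant_panel", "retinal_panel", "exclusion_panel",
                     "gwas_panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def stage_audit(cohort: Cohort, cfg: FilterConfig) -> dict:
    """Per-sample cumulative survival counts along the cascade."""
    per_sample = {s: dict.fromkeys(STAGES, 0) for s in cohort.samples}
    for v in cohort.variants:
        outcome = filter_variant(v, cfg)
        failed = set(outcome.failed_stages)
        quality_ok = not any(f.startswith("quality") for f in failed)
        maf_ok = "maf" not in failed
        csq_ok = "consequence" not in failed
        tier_ok = "tier" not in failed
        for s in v.carriers:
            counts = per_sample[s]
            counts["total"] += 1
            if quality_ok:
                counts["quality"] += 1
                if maf_ok:
                    counts["maf"] += 1
                    if csq_ok:
                        counts["consequence"] += 1
                        if tier_ok:
                            counts["tier"] += 1
    n = max(1, len(cohort.samples))
    means = {
        stage: round(sum(c[stage] for c in per_sample.values()) / n, 3)
        for stage in STAGES
    }
    return {"per_sample": per_sample, "cohort_means": means,
            "config": cfg.to_dict()}


def _load_panels(cfg: RunConfig) -> dict[str, GenePanel]:
    panels: dict[str, GenePanel] = {}
    if cfg.deafness_panel:
        panels["deafness"] = read_gene_panel(
            cfg.deafness_panel, dominant_path=cfg.dominant_panel, name="deafness")
    if cfg.retinal_panel:
        panels["retinal"] = read_gene_panel(cfg.retinal_panel, name="retinal")
    if cfg.exclusion_panel:
        panels["exclusion"] = read_gene_panel(
            cfg.exclusion_panel, is_exclusion=True, name="exclusion")
    if cfg.gwas_panel:
        panels["gwas"] = read_gene_panel(cfg.gwas_panel, name="gwas")
    return panels


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the report bundle.

    Returns the paths of everything written. Raises before any
    computation if a referenced input file is missing.
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_vcf(cfg.vcf, annotation_source=cfg.annotation_source,
                             sidecar_path=cfg.sidecar)
    manifest = read_manifest(cfg.manifest)
    unknown = [s for s in cohort.samples if s not in manifest.assignments]
    if unknown:
        raise ValueError(f"samples missing from manifest: {unknown}")
    panels = _load_panels(cfg)
    exclusion = panels.get("exclusion")
    deafness = panels.get("deafness")
    _log(f"cohort: {len(cohort.samples)} samples, {len(cohort)} variants, "
         f"subgroups {manifest.subgroup_sizes()}")

    outputs: dict[str, Path] = {}
    audit: dict[str, dict] = {}
    for preset_name in cfg.presets:
        fcfg = preset(preset_name, **cfg.preset_overrides.get(preset_name, {}))
        audit[preset_name] = stage_audit(cohort, fcfg)
        _log(f"[{preset_name}] mean surviving variants per stage: "
             f"{audit[preset_name]['cohort_means']}")

        if preset_name == "common":
            outputs.update(_common_reports(cohort, manifest, panels, fcfg, outdir))
        else:
            outputs.update(_rare_reports(cohort, panels, fcfg, outdir, preset_name))

    audit_path = outdir / "audit.json"
    with open(audit_path, "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["audit"] = audit_path
    return outputs


def _common_reports(cohort, manifest: CohortManifest, panels, fcfg,
                    outdir: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}
    exclusion = panels.get("exclusion")
    deafness = panels.get("deafness")
    disease_panels = {k: p for k, p in panels.items()
                      if k in ("deafness", "retinal")}
    if disease_panels:
        grid = burden_grid(cohort, disease_panels, base_cfg=fcfg,
                           exclusion_panel=exclusion)
        rows = [
            {
                "panel": d.panel_name, "maf_threshold": d.maf_threshold,
                "tier": d.tier, "sample_id": s, "n_genes_hit": n,
            }
            for d in grid for s, n in sorted(d.per_individual.items())
        ]
        path = outdir / "burden_grid.tsv"
        write_report(rows, path)
        out["burden_grid"] = path
    if deafness and deafness.dominant_subset:
        summary = dominant_carrier_summary(cohort, deafness, fcfg)
        path = outdir / "dominant_carriers.tsv"
        write_report(summary, path)
        out["dominant_carriers"] = path
    shared_rows = []
    for subgroup in manifest.subgroups:
        for r in discovery.shared_mutated_genes(
                cohort, manifest, subgroup, fcfg,
                deafness_panel=deafness, exclusion_panel=exclusion):
            shared_rows.append({
                "gene": r.gene, "subgroup": r.subgroup,
                "n_variants": r.n_distinct_variants,
                "variant_types": r.variant_type_summary,
                "deafness_flag": r.deafness_flag,
                "exclusion_flag": r.exclusion_flag,
            })
    path = outdir / "shared_genes.tsv"
    write_report(shared_rows, path,
                 columns=["gene", "subgroup", "n_variants", "variant_types",
                          "deafness_flag", "exclusion_flag"])
    out["shared_genes"] = path
    return out


def _rare_reports(cohort, panels, fcfg, outdir: Path, preset_name: str) -> dict[str, Path]:
    out: dict[str, Path] = {}
    exclusion = panels.get("exclusion")
    deafness = panels.get("deafness")
    tag = preset_name

    rows = [
        {"gene": r.gene, "n_individuals": r.n_individuals,
         "sample_ids": r.sample_ids, "deafness_flag": r.deafness_flag,
         "exclusion_flag": r.exclusion_flag}
        for r in discovery.recurrent_genes(
            cohort, fcfg, deafness_panel=deafness, exclusion_panel=exclusion)
    ]
    path = outdir / f"recurrent_genes_{tag}.tsv"
    write_report(rows, path)
    out[f"recurrent_genes_{tag}"] = path

    rows = [
        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
         "gene": v.gene, "n_individuals": len(samples), "sample_ids": samples}
        for v, samples in discovery.recurrent_identical_variants(cohort, fcfg)
    ]
    path = outdir / f"recurrent_variants_{tag}.tsv"
    write_report(rows, path)
    out[f"recurrent_variants_{tag}"] = path

    hom = discovery.homozygous_rare(cohort, fcfg)
    rows = [
        {"sample_id": r.sample_id, "gene": r.gene, "chrom": r.variant.chrom,
         "pos": r.variant.pos, "ref": r.variant.ref, "alt": r.variant.alt,
         "note": r.note}
        for r in hom
    ]
    path = outdir / f"homozygous_{tag}.tsv"
    write_report(rows, path)
    out[f"homozygous_{tag}"] = path
    multi_person = discovery.multi_person_homozygous_genes(hom)
    rows = [{"gene": g, "sample_ids": s} for g, s in multi_person.items()]
    path = outdir / f"homozygous_multi_person_{tag}.tsv"
    write_report(rows, path)
    out[f"homozygous_multi_person_{tag}"] = path

    rows = [
        {"sample_id": r.sample_id, "gene": r.gene, "n_variants": r.n_variants,
         "zygosities": r.zygosities,
         "same_chromosome_evidence": r.same_chromosome_evidence}
        for r in discovery.multi_hit_genes(cohort, fcfg)
    ]
    path = outdir / f"multi_hit_{tag}.tsv"
    write_report(rows, path)
    out[f"multi_hit_{tag}"] = path

    if "gwas" in panels and len(panels["gwas"]):
        rows = [
            {"gene": h.gene, "chrom": h.variant.chrom, "pos": h.variant.pos,
             "ref": h.variant.ref, "alt": h.variant.alt,
             "sample_ids": h.sample_ids, "zygosities": h.zygosities}
            for h in discovery.candidate_lookup(cohort, fcfg, panels["gwas"])
        ]
        path = outdir / f"gwas_candidates_{tag}.tsv"
        write_report(rows, path)
        out[f"gwas_candidates_{tag}"] = path
    return out
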