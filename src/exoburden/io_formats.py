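"""Reading and writing the formats the pipeline touches.

* multi-sample VCF 4.x cohorts (via pysam), with annotations either
  inline as INFO fields or in a sidecar TSV keyed by chrom/pos/ref/alt
  (the sidecar wins on conflict);
* gene panels as newline-delimited symbol lists (or first TSV column);
* cohort manifests as two-column TSV (sample_id, subgroup);
* analysis reports as TSV or JSON with deterministic column order.

Multiallelic VCF records are decomposed into one record per alternate
allele. Variants whose annotations cannot be found are kept with explicit
"unknown" markers, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import pysam

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


class VcfParseError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationSchema:
    """Where annotations live in a VCF / sidecar table.

    Inline: INFO keys (``gene_key``, ``consequence_key``, one Float key
    per population named ``frequency_prefix + population``, and a single
    string key of ``name:verdict`` pairs joined by '|').
    Sidecar TSV: columns chrom, pos, ref, alt, gene, consequence, one
    ``af_<POP>`` column per population and one ``pred_<NAME>`` column
    per predictor.
    """

    gene_key: str = "GENE"
    consequence_key: str = "CSQ"
    frequency_prefix: str = "AF_"
    predictor_key: str = "PRED"
    sidecar_freq_prefix: str = "af_"
    sidecar_pred_prefix: str = "pred_"


DEFAULT_SCHEMA = AnnotationSchema()


def _parse_consequence(raw: str | None) -> Consequence:
    if not raw:
        return Consequence.UNKNOWN
    try:
        return Consequence(str(raw).strip().lower())
    except ValueError:
        return Consequence.OTHER


def _parse_predictor_string(raw: str | None) -> list[PredictorCall]:
    calls: list[PredictorCall] = []
    if not raw:
        return calls
    for item in str(raw).split("|"):
        item = item.strip()
        if not item:
            continue
        name, _, verdict = item.partition(":")
        try:
            v = Verdict(verdict.strip().lower())
        except ValueError:
            v = Verdict.UNKNOWN
        calls.append(PredictorCall(predictor_name=name.strip(), verdict=v))
    return calls


def _zygosity_from_gt(gt, alt_index: int) -> Zygosity:
    """Zygosity of one sample w.r.t. alternate allele ``alt_index`` (1-based)."""
    if gt is None or all(a is None for a in gt):
        return Zygosity.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return Zygosity.REFERENCE
    if n_alt >= len([a for a in gt if a is not None]) and n_alt >= 2:
        return Zygosity.HOMOZYGOUS_ALT
    if len(gt) == 1 and n_alt == 1:
        # haploid call: a single alt allele is hemizygous-compatible,
        # reported as homozygous_alt (the "apparently homozygous" caveat)
        return Zygosity.HOMOZYGOUS_ALT
    return Zygosity.HETEROZYGOUS


def _info_scalar(rec, key: str, alt_index0: int):
    """INFO value for one alt: per-allele tuples indexed, scalars shared."""
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, tuple):
        if alt_index0 < len(val):
            return val[alt_index0]
        return val[0] if val else None
    return val


def read_cohort_vcf(
    path: str | Path,
    annotation_source: str = "inline",
    sidecar_path: str | Path | None = None,
    schema: AnnotationSchema = DEFAULT_SCHEMA,
) -> Cohort:
    """Read a multi-sample VCF into a :class:`Cohort`.

    ``annotation_source`` is "inline" (annotations from INFO fields) or
    "sidecar" (from a TSV keyed by chrom/pos/ref/alt). Multiallelic
    records are decomposed into one :class:`AnnotatedVariant` per
    alternate allele; sites missing from the sidecar get unknown
    consequence and empty predictor calls, with a warning.
    """
    if annotation_source not in ("inline", "sidecar"):
        raise ValueError("annotation_source must be 'inline' or 'sidecar'")
    sidecar: dict[tuple, dict] | None = None
    if annotation_source == "sidecar":
        if sidecar_path is None:
            raise ValueError("sidecar annotation source requires sidecar_path")
        sidecar = _read_sidecar(sidecar_path, schema)

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    variants: list[AnnotatedVariant] = []
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                genotypes = {
                    s: _zygosity_from_gt(rec.samples[s].get("GT"), i + 1)
                    for s in samples
                }
                dp = _info_scalar(rec, "DP", i)
                mq = _info_scalar(rec, "MQ", i)
                v = AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=str(alt),
                    site_quality=rec.qual,
                    read_depth=int(dp) if dp is not None else None,
                    mapping_quality=float(mq) if mq is not None else None,
                    variant_id=rec.id,
                    genotypes=genotypes,
                )
                if sidecar is not None:
                    _annotate_from_sidecar(v, sidecar, path)
                else:
                    _annotate_from_info(v, rec, i, schema)
                variants.append(v)
    return Cohort(samples=samples, variants=variants)


def _annotate_from_info(v: AnnotatedVariant, rec, alt_index0: int,
                        schema: AnnotationSchema) -> None:
    gene = _info_scalar(rec, schema.gene_key, alt_index0)
    v.gene = str(gene).upper() if gene else ""
    v.consequence = _parse_consequence(_info_scalar(rec, schema.consequence_key, alt_index0))
    v.predictor_calls = _parse_predictor_string(
        _info_scalar(rec, schema.predictor_key, alt_index0)
    )
    freqs: dict[str, float] = {}
    for key in rec.info.keys():
        if key.startswith(schema.frequency_prefix):
            val = _info_scalar(rec, key, alt_index0)
            if val is not None:
                freqs[key[len(schema.frequency_prefix):]] = float(val)
    v.frequencies = freqs


def _read_sidecar(path: str | Path, schema: AnnotationSchema) -> dict[tuple, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"sidecar {path} missing key columns {sorted(required - set(df.columns))}")
    table: dict[tuple, dict] = {}
    for row in df.to_dict("records"):
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        table[key] = row
    return table


def _annotate_from_sidecar(v: AnnotatedVariant, sidecar: dict[tuple, dict],
                           vcf_path, schema: AnnotationSchema = DEFAULT_SCHEMA) -> None:
    row = sidecar.get(v.key)
    if row is None:
        warnings.warn(
            f"no sidecar annotation for {v.chrom}:{v.pos} {v.ref}>{v.alt}; "
            "keeping variant with unknown markers"
        )
        v.gene = ""
        v.consequence = Consequence.UNKNOWN
        v.predictor_calls = []
        v.frequencies = {}
        return
    v.gene = str(row.get("gene", "")).upper()
    v.consequence = _parse_consequence(row.get("consequence"))
    freqs: dict[str, float] = {}
    calls: list[PredictorCall] = []
    for col, val in row.items():
        if col.startswith(schema.sidecar_freq_prefix) and str(val) != "":
            freqs[col[len(schema.sidecar_freq_prefix):]] = float(val)
        elif col.startswith(schema.sidecar_pred_prefix) and str(val) != "":
            try:
                verdict = Verdict(str(val).strip().lower())
            except ValueError:
                verdict = Verdict.UNKNOWN
            calls.append(PredictorCall(col[len(schema.sidecar_pred_prefix):], verdict))
    v.frequencies = freqs
    v.predictor_calls = calls


# ---------------------------------------------------------------------------
# VCF writing (used by the synthetic generator and for round-trips)

_ZYG_TO_GT = {
    Zygosity.REFERENCE: (0, 0),
    Zygosity.HETEROZYGOUS: (0, 1),
    Zygosity.HOMOZYGOUS_ALT: (1, 1),
    Zygosity.MISSING: (None, None),
}


def write_cohort_vcf(
    cohort: Cohort,
    path: str | Path,
    schema: AnnotationSchema = DEFAULT_SCHEMA,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a cohort as an uncompressed VCF with inline annotations."""
    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    if contig_lengths:
        contigs.update(contig_lengths)
    for v in cohort.variants:
        need = v.pos + len(v.ref) + 1
        if contigs.get(v.chrom, 0) < need:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), need + 100_000)
    for name in sorted(contigs):
        header.contigs.add(name, length=contigs[name])
    header.info.add("DP", 1, "Integer", "Read depth at the site")
    header.info.add("MQ", 1, "Float", "Mapping quality")
    header.info.add(schema.gene_key, 1, "String", "Gene symbol")
    header.info.add(schema.consequence_key, 1, "String", "Consequence class")
    header.info.add(schema.predictor_key, 1, "String",
                    "Predictor verdicts, name:verdict pairs joined by |")
    pops = sorted({p for v in cohort.variants for p in v.frequencies})
    for pop in pops:
        header.info.add(f"{schema.frequency_prefix}{pop}", 1, "Float",
                        f"Minor allele frequency in population {pop}")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in cohort.samples:
        header.add_sample(s)

    order = {name: i for i, name in enumerate(sorted(contigs))}
    variants = sorted(cohort.variants, key=lambda v: (order[v.chrom], v.pos, v.ref, v.alt))

    out = pysam.VariantFile(str(path), "w", header=header)
    with out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), id=v.variant_id or None,
            )
            rec.qual = v.site_quality
            if v.read_depth is not None:
                rec.info["DP"] = v.read_depth
            if v.mapping_quality is not None:
                rec.info["MQ"] = v.mapping_quality
            if v.gene:
                rec.info[schema.gene_key] = v.gene
            rec.info[schema.consequence_key] = v.consequence.value
            if v.predictor_calls:
                rec.info[schema.predictor_key] = "|".join(
                    f"{c.predictor_name}:{c.verdict.value}" for c in v.predictor_calls
                )
            for pop, maf in v.frequencies.items():
                rec.info[f"{schema.frequency_prefix}{pop}"] = maf
            for s in cohort.samples:
                rec.samples[s]["GT"] = _ZYG_TO_GT[v.zygosity_of(s)]
            out.write(rec)


def write_sidecar(cohort: Cohort, path: str | Path,
                  schema: AnnotationSchema = DEFAULT_SCHEMA) -> None:
    """Write the cohort's annotations as a sidecar TSV (full precision)."""
    pops = sorted({p for v in cohort.variants for p in v.frequencies})
    preds = sorted({c.predictor_name for v in cohort.variants for c in v.predictor_calls})
    rows = []
    for v in sorted(cohort.variants, key=lambda v: v.key):
        row: dict[str, Any] = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "consequence": v.consequence.value,
        }
        for pop in pops:
            row[f"{schema.sidecar_freq_prefix}{pop}"] = (
                repr(v.frequencies[pop]) if pop in v.frequencies else ""
            )
        verdicts = {c.predictor_name: c.verdict.value for c in v.predictor_calls}
        for p in preds:
            row[f"{schema.sidecar_pred_prefix}{p}"] = verdicts.get(p, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene panels and manifests

def read_gene_panel(
    path: str | Path,
    dominant_path: str | Path | None = None,
    is_exclusion: bool = False,
    name: str | None = None,
) -> GenePanel:
    """Read a curated gene list: one symbol per line or first TSV column.

    Symbols are upper-cased and deduplicated; lines starting with '#'
    are comments. An empty file is an error.
    """
    genes = _read_symbols(path)
    if not genes:
        raise ValueError(f"gene panel {path} contains no symbols")
    dominant = _read_symbols(dominant_path) if dominant_path else []
    return GenePanel.from_symbols(
        name=name or Path(path).stem,
        genes=genes,
        dominant_subset=dominant,
        is_exclusion_list=is_exclusion,
    )


def _read_symbols(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].strip())
    return out


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest TSV with sample_id and subgroup columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "subgroup"} <= set(df.columns):
        raise ValueError(f"manifest {path} needs sample_id and subgroup columns")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id in manifest: {dups}")
    if df["subgroup"].isna().any() or (df["subgroup"].fillna("") == "").any():
        raise ValueError(f"manifest {path} has empty subgroup entries")
    return CohortManifest(assignments=dict(zip(df["sample_id"], df["subgroup"])))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(manifest.assignments),
         "subgroup": list(manifest.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports

def _normalize_records(result: Any) -> list[dict]:
    if result is None:
        return []
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        return [dataclasses.asdict(result)]
    if isinstance(result, Mapping):
        return [dict(result)]
    records = []
    for item in result:
        if dataclasses.is_dataclass(item) and not isinstance(item, type):
            records.append(dataclasses.asdict(item))
        elif isinstance(item, Mapping):
            records.append(dict(item))
        else:
            raise TypeError(f"cannot serialize report item of type {type(item)!r}")
    return records


def _stringify(value: Any) -> Any:
    if isinstance(value, (list, tuple, set, frozenset)):
        return ",".join(str(_stringify(x)) for x in sorted(value, key=str))
    if isinstance(value, dict):
        return ";".join(f"{k}={_stringify(v)}" for k, v in sorted(value.items(), key=lambda kv: str(kv[0])))
    if hasattr(value, "value") and not isinstance(value, (int, float)):
        return value.value
    return value

def write_report(result: Any, path: str | Path, format: str = "tsv",
                 columns: Iterable[str] | None = None) -> None:
    """Write an analysis result as TSV or JSON.

    Column order is deterministic (field order of the first record, or an
    explicit ``columns`` list); flag columns such as the exclusion-candidate
    marker are preserved, never dropped. Writing the same result twice
    yields byte-identical files.
    """
    records = _normalize_records(result)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError("format must be 'tsv' or 'json'")
    if columns is None:
        cols: list[str] = []
        for rec in records:
            for c in rec:
                if c not in cols:
                    cols.append(c)
    else:
        cols = list(columns)
    flat = [{c: _stringify(rec.get(c, "")) for c in cols} for rec in records]
    df = pd.DataFrame(flat, columns=cols)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Packaged panel fixtures

_PANEL_FILES = {
    "deafness": ("synthetic_deafness_genes.txt", "synthetic_dominant_deafness_genes.txt", False),
    "retinal": ("synthetic_retinal_genes.txt", None, False),
    "exclusion": ("synthetic_exclusion_candidates.txt", None, True),
    "gwas": ("gwas_candidate_genes.txt", None, False),
}


def load_default_panels() -> dict[str, GenePanel]:
    """Load the packaged gene-panel fixtures.

    The deafness (357 genes, dominant subset 33), retinal (265) and
    exclusion-candidate (507) lists are synthetic stand-ins at the sizes
    of the study's curated lists, seeded with the gene symbols the study
    names; the 8 GWAS candidate genes are the real symbols.
    """
    data = importlib.resources.files("exoburden.data")
    panels: dict[str, GenePanel] = {}
    for key, (fname, dom_fname, is_excl) in _PANEL_FILES.items():
        genes = [l.split("\t")[0].strip() for l in (data / fname).read_text().splitlines()
                 if l.strip() and not l.startswith("#")]
        dom = []
        if dom_fname:
            dom = [l.strip() for l in (data / dom_fname).read_text().splitlines()
                   if l.strip() and not l.startswith("#")]
        panels[key] = GenePanel.from_symbols(key, genes, dom, is_exclusion_list=is_excl)
    return panels
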