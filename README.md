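# exoburden

Rare-variant prioritisation and gene-panel burden analysis for
whole-exome cohorts, with a fully seeded synthetic-cohort generator for
validating every analysis against a known truth table.

## The problem

Exome studies of small, phenotypically structured cohorts (for example,
adults with progressive sensorineural hearing loss grouped by audiogram
shape) face two intertwined tasks:

1. **Prioritisation.** Out of tens of thousands of coding variants per
   individual, keep only those plausibly pathogenic: well-supported
   calls, rare in reference populations, protein-altering, and judged
   deleterious by in-silico predictors.
2. **Burden and discovery.** Ask whether individuals carry an excess of
   qualifying variants in curated disease-gene panels, which candidate
   genes recur across unrelated individuals, which are shared by every
   member of a phenotype subgroup, and which individuals carry
   homozygous or compound-heterozygous-like hits.

`exoburden` implements both as a library, plus a thin `exoburden` CLI.
Because real cohorts lack ground truth, the package includes a
deterministic synthetic-cohort generator that plants known facts
(subgroup-shared genes, recurrent identical variants, homozygotes,
multi-hit genes) and writes a machine-readable truth table, so the
whole pipeline can be tested end to end.

## The model

Variants flow through a four-stage cascade (`exoburden.filtering`):

- **Quality gate** — site quality ≥ 30, read depth ≥ 20, mapping
  quality ≥ 45 (disableable for pre-validated call sets).
- **Frequency gate** — minor allele frequency from a primary reference
  population (default `NFE`), falling back to a secondary population
  (`EUR_1KG`) and finally to 0 for novel variants. Tiered thresholds:
  ≤ 10 % and ≤ 1 % (inclusive), < 0.5 % and < 0.05 % (exclusive).
- **Consequence gate** — retain loss-of-function classes plus missense,
  in-frame indels and splice-region changes.
- **Pathogenicity tiers** — predictor votes with unknowns excluded:
  `majority`, `all` (unanimous), and `lof_only`; LoF consequences pass
  all tiers without predictor support. Tiers are provably nested.

Burden (`exoburden.burden`) counts *distinct* panel genes with at least
one passing carried variant per individual, zygosity ignored;
distributions are compared with a Mann–Whitney U test. Discovery
(`exoburden.discovery`) finds subgroup-shared genes, recurrent
genes/identical variants, apparently homozygous rare variants,
multi-hit genes (with a 100 bp read-window phase heuristic), and
candidate-gene lookups.

## Worked example

```bash
python examples/simulate_cohort.py
python examples/burden_profile.py
python examples/discovery_screen.py
```

`burden_profile.py` prints, for a seed-7 default cohort of 30 samples:

```
majority  tier: min 10, mean 10.0, max 11 deafness genes hit; 30/30 carriers
all       tier: min 6, mean 8.6, max 10 deafness genes hit; 30/30 carriers
lof_only  tier: min 0, mean 0.2, max 1 deafness genes hit; 6/30 carriers

dominant-gene subset (33 genes): 21/30 carry a predicted pathogenic variant,
1 carry a loss-of-function variant — candidates for monogenic follow-up.
```

and `discovery_screen.py` recovers every planted fact:

```
  Dominant  : DNAH2  -> expected DNAH2 (planted)
  Metabolic : MON1B  -> expected MON1B (planted)
  Recessive : TTN  -> expected TTN (planted)
  Sensory   : NEDD4  -> expected NEDD4 (planted)
identical very-rare variants in >=2 individuals: 5 (planted: 5)
```

The same analyses are available from the command line:

```bash
exoburden simulate --seed 7 --out cohort/
exoburden recurrent --vcf cohort/cohort.vcf --preset very_rare --out recurrent.tsv
exoburden run --config run.yaml     # full report bundle + audit.json
```

## Layout

- `src/exoburden/` — library modules: `model`, `filtering`,
  `io_formats`, `burden`, `discovery`, `simulate`, `pipeline`, `cli`,
  and packaged gene-panel fixtures in `data/`.
- `examples/` — short narrative scripts (start here).
- `tests/` — unit, property-based (hypothesis) and acceptance tests,
  with an independent straight-line oracle in `tests/oracle.py`.
- `docs/methods.md` — model, parameters, numerical choices, and
  limitations.
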