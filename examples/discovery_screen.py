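"""Run the gene-discovery screens on a synthetic cohort and compare
what they find against the planted truth.

Shared genes use the lenient common preset (a variant shared by a whole
phenotype subgroup need not be rare); recurrent variants, homozygotes
and multi-hit genes use the very-rare preset (MAF < 0.5%).
"""

from exoburden import discovery
from exoburden.filtering import preset
from exoburden.simulate import SyntheticConfig, simulate_cohort

sim = simulate_cohort(SyntheticConfig(seed=7))
common, very_rare = preset("common"), preset("very_rare")

print("genes mutated in every member of each subgroup (common preset):")
for subgroup in sorted(sim.manifest.subgroups):
    recs = discovery.shared_mutated_genes(sim.cohort, sim.manifest,
                                          subgroup, common)
    planted = sim.truth.planted_shared_genes.get(subgroup)
    genes = sorted(r.gene for r in recs)
    mark = " (planted)" if planted in genes else ""
    print(f"  {subgroup:10s}: {', '.join(genes) or '-'}"
          f"  -> expected {planted}{mark}")

recurrent = discovery.recurrent_identical_variants(sim.cohort, very_rare)
print(f"\nidentical very-rare variants in >=2 individuals: {len(recurrent)} "
      f"(planted: {len(sim.truth.planted_recurrent)})")

hom = discovery.homozygous_rare(sim.cohort, very_rare)
print(f"apparently homozygous very-rare variants: {len(hom)} "
      f"(planted: {len(sim.truth.planted_homozygotes)})")

multi = discovery.multi_hit_genes(sim.cohort, very_rare)
for r in multi:
    print(f"multi-hit gene {r.gene} in {r.sample_id}: {r.n_variants} "
          f"variants, same-chromosome evidence {r.same_chromosome_evidence}")

gwas = discovery.candidate_lookup(sim.cohort, very_rare, sim.panels["gwas"])
print(f"\nvery-rare variants in GWAS candidate genes: {len(gwas)}")
for hit in gwas:
    print(f"  {hit.gene} {hit.variant.chrom}:{hit.variant.pos} "
          f"carried by {', '.join(hit.carriers)}")
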