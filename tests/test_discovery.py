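"""Subgroup sharing, recurrence, homozygosity, multi-hit and candidate
lookup analyses."""

import random
from collections import defaultdict

import pytest

from exoburden import discovery
from exoburden.filtering import FilterConfig, filter_variant, preset
from exoburden.io_formats import load_default_panels
from exoburden.model import Cohort, CohortManifest, Consequence, GenePanel, Zygosity
from exoburden.simulate import SyntheticConfig, simulate_cohort

from conftest import make_variant

SENSORY = [f"Sensory{i:02d}" for i in range(1, 6)]
MANIFEST = CohortManifest(assignments={**{s: "Sensory" for s in SENSORY},
                                       "Dominant01": "Dominant",
                                       "Dominant02": "Dominant"})
ALL_SAMPLES = list(MANIFEST.assignments)


def _cohort(variants):
    return Cohort(samples=ALL_SAMPLES, variants=list(variants))


class TestSharedMutatedGenes:
    def test_gene_in_every_member_is_reported(self):
        variants = [make_variant(gene="NEDD4", carriers=(s,)) for s in SENSORY]
        recs = discovery.shared_mutated_genes(
            _cohort(variants), MANIFEST, "Sensory", FilterConfig())
        assert [r.gene for r in recs] == ["NEDD4"]

    def test_four_of_five_members_is_not_shared(self):
        variants = [make_variant(gene="NEDD4", carriers=(s,)) for s in SENSORY[:4]]
        recs = discovery.shared_mutated_genes(
            _cohort(variants), MANIFEST, "Sensory", FilterConfig())
        assert recs == []

    def test_record_shape_for_two_missense_variants(self):
        """Two distinct non-synonymous variants covering all five sensory
        members yield one record: gene, subgroup, 2 variants, summary."""
        v1 = make_variant(gene="NEDD4", carriers=tuple(SENSORY[:3]))
        v2 = make_variant(gene="NEDD4", carriers=tuple(SENSORY[2:]))
        panels = load_default_panels()
        recs = discovery.shared_mutated_genes(
            _cohort([v1, v2]), MANIFEST, "Sensory", FilterConfig(),
            deafness_panel=panels["deafness"],
            exclusion_panel=panels["exclusion"])
        assert len(recs) == 1
        r = recs[0]
        assert (r.gene, r.subgroup, r.n_distinct_variants) == ("NEDD4", "Sensory", 2)
        assert r.variant_type_summary == "2 non-synonymous"
        assert not r.deafness_flag and not r.exclusion_flag

    def test_unknown_subgroup_is_error(self):
        with pytest.raises(KeyError):
            discovery.shared_mutated_genes(
                _cohort([]), MANIFEST, "Vestibular", FilterConfig())

    def test_exclusion_candidate_flagged_not_dropped(self):
        excl = GenePanel.from_symbols("excl", ["TTN"], is_exclusion_list=True)
        variants = [make_variant(gene="TTN", carriers=(s,)) for s in SENSORY]
        recs = discovery.shared_mutated_genes(
            _cohort(variants), MANIFEST, "Sensory", FilterConfig(),
            exclusion_panel=excl)
        assert len(recs) == 1 and recs[0].exclusion_flag


class TestRecurrentGenes:
    def test_matches_brute_force_per_gene_counting(self):
        cfg = SyntheticConfig(
            seed=17, subgroup_sizes={"Dominant": 4, "Sensory": 3},
            n_background_genes=40, min_panel_hits=3,
            planted_shared_genes={}, planted_recurrent_variants=2,
            planted_homozygotes=1, planted_multi_hit=(),
        )
        sim = simulate_cohort(cfg)
        fcfg = preset("very_rare")
        # brute force: per-gene set of carrier samples over passing variants
        expected: dict[str, set] = defaultdict(set)
        for v in sim.cohort.variants:
            if v.gene and filter_variant(v, fcfg).passed:
                expected[v.gene].update(v.carriers)
        expected = {g: s for g, s in expected.items() if len(s) >= 2}
        got = {r.gene: set(r.sample_ids)
               for r in discovery.recurrent_genes(sim.cohort, fcfg)}
        assert got == expected

    def test_single_carrier_gene_absent(self):
        v = make_variant(gene="GPR98", carriers=("Sensory01",))
        assert discovery.recurrent_genes(_cohort([v]), FilterConfig()) == []

    def test_carrier_count_and_ordering(self):
        variants = [make_variant(gene="GPR98", carriers=(s,)) for s in SENSORY[:5]]
        variants += [make_variant(gene="WFS1", carriers=("Dominant01", "Dominant02"))]
        recs = discovery.recurrent_genes(_cohort(variants), FilterConfig())
        assert [(r.gene, r.n_individuals) for r in recs] == [("GPR98", 5), ("WFS1", 2)]


class TestRecurrentIdenticalVariants:
    def test_shared_snv_reported_with_both_samples(self):
        v = make_variant(gene="MON1B", carriers=("Sensory01", "Dominant01"))
        out = discovery.recurrent_identical_variants(_cohort([v]), FilterConfig())
        assert len(out) == 1
        assert out[0][1] == ("Dominant01", "Sensory01")

    def test_different_alt_at_same_position_not_merged(self):
        v1 = make_variant(gene="MON1B", pos=500, alt="G", carriers=("Sensory01",))
        v2 = make_variant(gene="MON1B", pos=500, alt="T", carriers=("Sensory02",))
        out = discovery.recurrent_identical_variants(_cohort([v1, v2]), FilterConfig())
        assert out == []

    def test_planted_recurrent_variants_recovered_with_exact_carriers(self):
        cfg = SyntheticConfig(
            seed=23, subgroup_sizes={"Dominant": 5, "Recessive": 5},
            n_background_genes=50, min_panel_hits=3,
            planted_shared_genes={}, planted_recurrent_variants=4,
            planted_homozygotes=0, planted_multi_hit=(),
        )
        sim = simulate_cohort(cfg)
        out = {v.key: samples for v, samples in
               discovery.recurrent_identical_variants(sim.cohort, preset("very_rare"))}
        for rec in sim.truth.planted_recurrent:
            key = tuple(rec["key"])
            assert key in out
            assert list(out[key]) == rec["samples"]


class TestHomozygousRare:
    def test_het_only_cohort_is_empty(self):
        v = make_variant(gene="ZAN", carriers=("Sensory01",))
        assert discovery.homozygous_rare(_cohort([v]), FilterConfig()) == []

    def test_planted_homozygote_reported_with_caveat(self):
        v = make_variant(gene="ZAN", carriers=("Sensory01",),
                         zygosity=Zygosity.HOMOZYGOUS_ALT)
        recs = discovery.homozygous_rare(_cohort([v]), FilterConfig())
        assert len(recs) == 1
        assert recs[0].sample_id == "Sensory01"
        assert "apparently homozygous" in recs[0].note

    def test_multi_person_homozygous_section(self):
        v1 = make_variant(gene="SIRPA", carriers=("Sensory01",),
                          zygosity=Zygosity.HOMOZYGOUS_ALT)
        v2 = make_variant(gene="SIRPA", carriers=("Dominant01",),
                          zygosity=Zygosity.HOMOZYGOUS_ALT)
        v3 = make_variant(gene="ZAN", carriers=("Sensory02",),
                          zygosity=Zygosity.HOMOZYGOUS_ALT)
        recs = discovery.homozygous_rare(_cohort([v1, v2, v3]), FilterConfig())
        multi = discovery.multi_person_homozygous_genes(recs)
        assert multi == {"SIRPA": ["Dominant01", "Sensory01"]}


class TestMultiHitGenes:
    def test_five_variant_individual(self):
        variants = [make_variant(gene="WFS1", pos=1000 + 200 * i,
                                 carriers=("Dominant01",)) for i in range(5)]
        recs = discovery.multi_hit_genes(_cohort(variants), FilterConfig())
        assert len(recs) == 1
        assert (recs[0].sample_id, recs[0].gene, recs[0].n_variants) == \
            ("Dominant01", "WFS1", 5)
        assert recs[0].same_chromosome_evidence == "unknown"

    def test_close_pair_with_cis_phase_is_confirmed(self):
        v1 = make_variant(gene="GPR98", pos=5000, carriers=("Dominant01",))
        v2 = make_variant(gene="GPR98", pos=5040, carriers=("Dominant01",))
        recs = discovery.multi_hit_genes(
            _cohort([v1, v2]), FilterConfig(),
            phase_annotations={("Dominant01", "GPR98"): "cis"})
        assert recs[0].same_chromosome_evidence == "confirmed"

    def test_trans_phase_is_refuted(self):
        v1 = make_variant(gene="GPR98", pos=5000, carriers=("Dominant01",))
        v2 = make_variant(gene="GPR98", pos=5040, carriers=("Dominant01",))
        recs = discovery.multi_hit_genes(
            _cohort([v1, v2]), FilterConfig(),
            phase_annotations={("Dominant01", "GPR98"): "trans"})
        assert recs[0].same_chromosome_evidence == "refuted"

    def test_distant_pair_without_phase_stays_unknown(self):
        v1 = make_variant(gene="GPR98", pos=5000, carriers=("Dominant01",))
        v2 = make_variant(gene="GPR98", pos=9000, carriers=("Dominant01",))
        recs = discovery.multi_hit_genes(
            _cohort([v1, v2]), FilterConfig(),
            phase_annotations={("Dominant01", "GPR98"): "cis"})
        assert recs[0].same_chromosome_evidence == "unknown"

    def test_hits_in_different_genes_are_separate_records(self):
        v1 = make_variant(gene="GPR98", carriers=("Dominant01",))
        v2 = make_variant(gene="GPR98", carriers=("Dominant01",))
        v3 = make_variant(gene="WFS1", carriers=("Dominant01",))
        v4 = make_variant(gene="WFS1", carriers=("Dominant01",))
        recs = discovery.multi_hit_genes(_cohort([v1, v2, v3, v4]), FilterConfig())
        assert sorted((r.gene, r.n_variants) for r in recs) == \
            [("GPR98", 2), ("WFS1", 2)]


class TestCandidateLookup:
    def test_default_panel_has_eight_genes(self):
        assert len(load_default_panels()["gwas"]) == 8

    def test_no_candidate_variants_yields_empty(self):
        v = make_variant(gene="NEDD4", carriers=("Sensory01",))
        out = discovery.candidate_lookup(_cohort([v]), FilterConfig(),
                                         load_default_panels()["gwas"])
        assert out == []

    def test_variant_shared_by_two_samples_is_one_row(self):
        v = make_variant(gene="ACAN", carriers=("Sensory01", "Dominant01"))
        out = discovery.candidate_lookup(_cohort([v]), FilterConfig(),
                                         load_default_panels()["gwas"])
        assert len(out) == 1
        assert out[0].sample_ids == ("Dominant01", "Sensory01")

    def test_empty_panel_is_error(self):
        empty = GenePanel.from_symbols("none", [])
        with pytest.raises(ValueError):
            discovery.candidate_lookup(_cohort([]), FilterConfig(), empty)


def test_shared_genes_subset_of_recurrent_restricted_to_subgroup():
    """A gene shared by all m members of a subgroup is necessarily a
    recurrent gene at min_individuals=m within those members."""
    cfg = SyntheticConfig(
        seed=31, subgroup_sizes={"Sensory": 4, "Dominant": 3},
        n_background_genes=60, min_panel_hits=4, per_gene_hit_prob=0.05,
        planted_shared_genes={"Sensory": "NEDD4"},
        planted_recurrent_variants=0, planted_homozygotes=0,
        planted_multi_hit=(),
    )
    sim = simulate_cohort(cfg)
    fcfg = preset("common")
    members = set(sim.manifest.members("Sensory"))
    shared = {r.gene for r in discovery.shared_mutated_genes(
        sim.cohort, sim.manifest, "Sensory", fcfg)}
    recurrent = {
        r.gene for r in discovery.recurrent_genes(sim.cohort, fcfg,
                                                  min_individuals=1)
        if len(members & set(r.sample_ids)) >= len(members)
    }
    assert shared <= recurrent
    assert "NEDD4" in shared


def test_discovery_outputs_order_independent():
    variants = [
        make_variant(gene="GPR98", carriers=("Sensory01", "Sensory02")),
        make_variant(gene="WFS1", carriers=("Dominant01",)),
        make_variant(gene="WFS1", carriers=("Dominant01",)),
        make_variant(gene="ZAN", carriers=("Sensory03",),
                     zygosity=Zygosity.HOMOZYGOUS_ALT),
    ]
    shuffled = list(variants)
    random.Random(3).shuffle(shuffled)
    cfg = FilterConfig()
    a, b = _cohort(variants), _cohort(shuffled)
    assert discovery.recurrent_genes(a, cfg) == discovery.recurrent_genes(b, cfg)
    assert discovery.multi_hit_genes(a, cfg) == discovery.multi_hit_genes(b, cfg)
    assert [(r.sample_id, r.gene) for r in discovery.homozygous_rare(a, cfg)] == \
        [(r.sample_id, r.gene) for r in discovery.homozygous_rare(b, cfg)]
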