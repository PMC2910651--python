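import numpy as np
import pytest

from crmrank.scoring import (
    BackgroundModel,
    ClusterModel,
    cluster_score,
    scan_sites,
)
from crmrank.simulate import (
    SyntheticSpec,
    ablate_sites,
    ebox_core_pwm,
    generate_bundle,
    implant_clusters,
    implant_pwm,
    make_library,
    sample_genome,
)

SMALL = dict(n_genes=120, region_length_bp=400, n_species=3, n_target_genes=15,
             sites_per_cluster=3, cluster_window_bp=200)


class TestSpecValidation:
    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            SyntheticSpec(bg_substitution_rate=1.4)

    def test_sites_must_be_conserved(self):
        with pytest.raises(ValueError):
            SyntheticSpec(bg_substitution_rate=0.05, site_substitution_rate=0.2)

    def test_targets_bounded_by_genes(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_genes=10, n_target_genes=11)


class TestSampleGenome:
    def test_same_seed_is_byte_identical(self):
        spec = SyntheticSpec(**SMALL, seed=5)
        assert sample_genome(spec) == sample_genome(spec)

    def test_different_seed_differs(self):
        a = sample_genome(SyntheticSpec(**SMALL, seed=5))
        b = sample_genome(SyntheticSpec(**SMALL, seed=6))
        assert a != b

    def test_base_composition_within_three_se(self):
        spec = SyntheticSpec(n_genes=100, region_length_bp=10_000, n_species=1,
                             n_target_genes=1, seed=3)
        seqs = sample_genome(spec)
        joined = "".join(seqs.values())
        n = len(joined)
        for base, freq in zip("ACGT", spec.background_frequencies):
            obs = joined.count(base) / n
            se = np.sqrt(freq * (1 - freq) / n)
            assert abs(obs - freq) <= 3 * se + 1e-6

    def test_degenerate_frequencies_floored(self):
        spec = SyntheticSpec(**SMALL, background_frequencies=(1.0, 0.0, 0.0, 0.0), seed=1)
        seqs = sample_genome(spec)
        assert set("".join(seqs.values())) <= set("ACGT")


@pytest.fixture(scope="module")
def implanted():
    # enough targets that the >=90% site-recovery property is measured
    # on ~150 sites rather than dominated by small-sample noise
    spec = SyntheticSpec(n_genes=200, region_length_bp=400, n_species=3,
                         n_target_genes=50, sites_per_cluster=3,
                         cluster_window_bp=200, seed=11)
    ref = sample_genome(spec)
    seqs, log = implant_clusters(ref, implant_pwm(), spec)
    return spec, seqs, log


class TestImplantClusters:
    def test_exact_site_count_per_target(self, implanted):
        spec, _, log = implanted
        per_region = {}
        for e in log.reference_sites():
            per_region.setdefault(e["region_id"], []).append(e)
        assert len(per_region) == spec.n_target_genes
        assert all(len(v) == spec.sites_per_cluster for v in per_region.values())

    def test_logged_sites_nonoverlapping_and_match_sequence(self, implanted):
        _, seqs, log = implanted
        for rid in {e["region_id"] for e in log.reference_sites()}:
            spans = sorted(
                (e["offset"], e["offset"] + len(e["site_seq"]), e["site_seq"])
                for e in log.sites_for("ref", rid)
            )
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
            for s, e, site in spans:
                assert seqs[rid][s:e] == site

    def test_scan_recovers_most_logged_sites_at_threshold(self, implanted):
        _, seqs, log = implanted
        bg = BackgroundModel.uniform()
        pwm = implant_pwm()
        hits = 0
        total = 0
        for e in log.reference_sites():
            total += 1
            found = scan_sites(pwm, bg, seqs[e["region_id"]], threshold_bits=6.0)
            if any(h.offset == e["offset"] for h in found):
                hits += 1
        assert hits / total >= 0.9

    def test_non_target_regions_untouched(self, implanted):
        spec, seqs, log = implanted
        targeted = {e["region_id"] for e in log.reference_sites()}
        ref = sample_genome(spec)
        for rid, seq in ref.items():
            if rid not in targeted:
                assert seqs[rid] == seq

    def test_window_too_small_is_error(self):
        spec = SyntheticSpec(n_genes=10, region_length_bp=100, n_target_genes=2,
                             sites_per_cluster=5, cluster_window_bp=30, n_species=1)
        ref = sample_genome(spec)
        with pytest.raises(ValueError, match="window"):
            implant_clusters(ref, implant_pwm(), spec)


class TestEvolveOrthologs:
    def test_zero_rates_give_identical_orthologs(self):
        spec = SyntheticSpec(**SMALL, bg_substitution_rate=0.0,
                             site_substitution_rate=0.0, seed=2)
        bundle = generate_bundle(spec)
        for rid, entry in bundle.orthology.mapping.items():
            for sid, orid in entry.items():
                assert bundle.sequences[sid][orid] == bundle.sequences["ref"][rid]

    def test_sites_more_conserved_than_background(self):
        spec = SyntheticSpec(**SMALL, bg_substitution_rate=0.3,
                             site_substitution_rate=0.02, seed=4)
        bundle = generate_bundle(spec)
        ident_in, n_in, ident_out, n_out = 0, 0, 0, 0
        for e in bundle.implant_log.entries:
            if e["species_id"] == "ref":
                continue
            rid = e["region_id"].split("@")[0]
            ref_site = bundle.sequences["ref"][rid][
                e["offset"]: e["offset"] + len(e["site_seq"])
            ]
            ident_in += sum(a == b for a, b in zip(ref_site, e["site_seq"]))
            n_in += len(ref_site)
        for rid, entry in bundle.orthology.mapping.items():
            if rid in {x["region_id"] for x in bundle.implant_log.reference_sites()}:
                continue
            for sid, orid in entry.items():
                if sid == "ref":
                    continue
                ref_seq = bundle.sequences["ref"][rid]
                sp_seq = bundle.sequences[sid][orid]
                ident_out += sum(a == b for a, b in zip(ref_seq, sp_seq))
                n_out += len(ref_seq)
        assert ident_in / n_in > ident_out / n_out

    def test_dropout_fraction_within_three_se(self):
        spec = SyntheticSpec(n_genes=400, region_length_bp=100, n_species=4,
                             n_target_genes=5, sites_per_cluster=2,
                             cluster_window_bp=60, dropout=0.2, seed=9)
        bundle = generate_bundle(spec)
        cells = [(rid, sid) for rid in bundle.orthology.mapping
                 for sid in spec.species_ids if sid != "ref"]
        missing = sum(
            1 for rid, sid in cells if sid not in bundle.orthology.mapping[rid]
        )
        p, n = 0.2, len(cells)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(missing / n - p) <= 3 * se

    def test_bundle_is_pure_function_of_spec(self):
        spec = SyntheticSpec(**SMALL, seed=21)
        b1, b2 = generate_bundle(spec), generate_bundle(spec)
        assert b1.sequences == b2.sequences
        assert b1.orthology.mapping == b2.orthology.mapping
        assert b1.gene_set.gene_ids == b2.gene_set.gene_ids
        assert b1.implant_log.entries == b2.implant_log.entries


class TestGeneSetMixture:
    def test_contamination_fraction(self):
        spec = SyntheticSpec(**SMALL, contamination=0.5, seed=8)
        bundle = generate_bundle(spec)
        targets = set(bundle.implant_log.target_genes)
        members = bundle.gene_set.gene_ids
        assert len(members) == 2 * spec.n_target_genes
        assert len(members & targets) == spec.n_target_genes


class TestAblateSites:
    def test_ebox_core_rule(self):
        # degenerate CANNTG model: CACGTG -> CGCGCG (columns 2 and 5, 1-based)
        pwm = ebox_core_pwm()
        seq = "TT" + "CACGTG" + "TT"
        from crmrank.scoring import SiteMatch

        site = SiteMatch("r", 2, "+", pwm.motif_id, 8.0)
        assert ablate_sites(seq, [site], pwm) == "TT" + "CGCGCG" + "TT"

    def test_minus_strand_site_ablated_through_strand(self):
        pwm = ebox_core_pwm()
        from crmrank.scoring import SiteMatch

        # revcomp(CACGTG) = CACGTG is palindromic; use CAGATG (revcomp CATCTG)
        seq = "TT" + "CATCTG" + "TT"  # minus-strand CAGATG site
        site = SiteMatch("r", 2, "-", pwm.motif_id, 8.0)
        out = ablate_sites(seq, [site], pwm)
        # plus-strand complement of the CANNTG->CGNNCG rule: CATCTG -> CGTCCG
        assert out == "TT" + "CGTCCG" + "TT"

    def test_empty_site_list_is_identity(self):
        assert ablate_sites("ACGTACGT", [], implant_pwm()) == "ACGTACGT"

    def test_ablation_always_reduces_cluster_score(self):
        spec = SyntheticSpec(**SMALL, seed=13)
        bundle = generate_bundle(spec)
        bg = BackgroundModel.uniform()
        pwm = implant_pwm()
        model = ClusterModel(motifs=[pwm])
        checked = 0
        for rid in sorted({e["region_id"] for e in bundle.implant_log.reference_sites()}):
            seq = bundle.sequences["ref"][rid]
            rs = cluster_score(model, bg, seq, region_id=rid)
            if not rs.sites_used:
                continue
            mutated = ablate_sites(seq, rs.sites_used, pwm)
            rs2 = cluster_score(model, bg, mutated, region_id=rid)
            assert rs2.score_bits < rs.score_bits
            checked += 1
        assert checked >= 10


class TestLibrary:
    def test_library_composition_and_determinism(self):
        lib1 = make_library(20, seed=3, implanted=implant_pwm())
        lib2 = make_library(20, seed=3, implanted=implant_pwm())
        assert len(lib1) == 20
        assert lib1.motif_ids[0] == "ebox_implant"
        for a, b in zip(lib1, lib2):
            np.testing.assert_array_equal(a.probs, b.probs)

    def test_implant_pwm_is_information_rich_nonpalindrome(self):
        pwm = implant_pwm()
        assert pwm.information_content().sum() > 8.0
        assert sorted(pwm.information_content())[-6] > 1.5  # sharp 6-column core
        assert not np.allclose(pwm.probs, pwm.reverse_complement().probs)
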