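import numpy as np
import pytest

from crmrank.pwm import Pwm
from crmrank.scoring import (
    BackgroundModel,
    ClusterModel,
    cluster_score,
    cluster_scores_batch,
    estimate_background,
    heterotypic_filter,
    reverse_complement,
    scan_sites,
    site_log_odds,
)

from .oracles import chain_cluster_score, random_motif, random_sequence, subset_cluster_score


def _single_base_pwm():
    # A-preferring single-position motif: probs (0.75, 1/12, 1/12, 1/12)
    return Pwm.from_counts("oneA", np.array([[8.0, 0, 0, 0]]), pseudocount=1.0)


class TestBackground:
    def test_balanced_sequence_is_uniform(self):
        bg = estimate_background(["ACGT"])
        np.testing.assert_allclose(bg.base_frequencies, 0.25)

    def test_strand_symmetrization_with_flooring(self):
        bg = estimate_background(["AAAA"])
        f = bg.base_frequencies
        # A and T share the symmetrized mass; C and G sit at the floor
        assert f[0] == f[3] and f[1] == f[2]
        assert f[1] == pytest.approx(1e-4 / (2 * 0.5 + 2 * 1e-4))
        assert f.sum() == pytest.approx(1.0)

    def test_all_n_is_error(self):
        with pytest.raises(ValueError):
            estimate_background(["NNNN"])

    def test_frequencies_floored(self):
        bg = BackgroundModel(np.array([1.0, 0.0, 0.0, 0.0]))
        assert (bg.base_frequencies >= 1e-4 / 1.1).all()


class TestSiteLogOdds:
    def test_uniform_pwm_scores_zero(self, uniform_bg):
        pwm = Pwm("u", np.full((3, 4), 0.25))
        assert site_log_odds(pwm, uniform_bg, "ACG") == pytest.approx(0.0)

    def test_hand_arithmetic_single_position(self, uniform_bg):
        assert site_log_odds(_single_base_pwm(), uniform_bg, "A") == pytest.approx(
            np.log2(3), abs=1e-12
        )

    def test_minus_strand_equals_forward_of_revcomp(self, uniform_bg, rng):
        pwm = random_motif(rng, 5)
        for _ in range(20):
            w = random_sequence(rng, 5)
            assert site_log_odds(pwm, uniform_bg, w, "+") == pytest.approx(
                site_log_odds(pwm, uniform_bg, reverse_complement(w), "-"), abs=1e-12
            )

    def test_length_mismatch_is_error(self, uniform_bg):
        with pytest.raises(ValueError):
            site_log_odds(_single_base_pwm(), uniform_bg, "AA")

    def test_n_in_window_gives_no_site(self, uniform_bg):
        pwm = random_motif(np.random.default_rng(0), 3)
        assert site_log_odds(pwm, uniform_bg, "ANG") == float("-inf")


class TestScanSites:
    def test_no_position_above_threshold(self, uniform_bg):
        pwm = Pwm("u", np.full((4, 4), 0.25))  # all scores 0 bits
        assert scan_sites(pwm, uniform_bg, "ACGTACGTACGT", threshold_bits=6.0) == []

    def test_implanted_consensus_found_at_offset(self, uniform_bg):
        from crmrank.simulate import implant_pwm

        pwm = implant_pwm()
        seq = "T" * 20 + pwm.consensus() + "T" * 20
        hits = scan_sites(pwm, uniform_bg, seq)
        assert [h.offset for h in hits] == [20]
        assert hits[0].strand == "+"

    def test_palindromic_site_reported_on_both_strands(self, uniform_bg):
        counts = np.zeros((6, 4))
        for j, b in enumerate("CACGTG"):  # palindromic consensus
            counts[j, "ACGT".index(b)] = 20
        pwm = Pwm.from_counts("pal", counts, pseudocount=0.25)
        seq = "TTTT" + "CACGTG" + "TTTT"
        hits = scan_sites(pwm, uniform_bg, seq)
        assert [(h.offset, h.strand) for h in hits] == [(4, "+"), (4, "-")]

    def test_sequence_shorter_than_motif_is_empty(self, uniform_bg):
        pwm = random_motif(np.random.default_rng(1), 8)
        assert scan_sites(pwm, uniform_bg, "ACG") == []


class TestClusterScore:
    def test_no_positive_site_floors_at_zero(self, uniform_bg):
        pwm = Pwm("u", np.full((4, 4), 0.25))
        rs = cluster_score(ClusterModel(motifs=[pwm]), uniform_bg, "ACGTACGT")
        assert rs.score_bits == 0.0 and rs.sites_used == [] and rs.best_window is None

    def test_single_site_scores_itself_without_gaps(self, uniform_bg):
        from crmrank.simulate import implant_pwm

        pwm = implant_pwm()
        cons = pwm.consensus()
        seq = "T" * 30 + cons + "T" * 30
        rs = cluster_score(ClusterModel(motifs=[pwm]), uniform_bg, seq)
        expected = site_log_odds(pwm, uniform_bg, cons)
        assert rs.score_bits == pytest.approx(expected, abs=1e-9)
        assert rs.best_window == (30, 30 + pwm.length)
        assert len(rs.sites_used) == 1

    def test_empty_sequence_is_error(self, uniform_bg):
        with pytest.raises(ValueError):
            cluster_score(ClusterModel(motifs=[_single_base_pwm()]), uniform_bg, "")

    def test_matches_chain_oracle_on_random_cases(self, uniform_bg, rng):
        for _ in range(60):
            n_motifs = int(rng.integers(1, 4))
            motifs = [random_motif(rng, int(rng.integers(2, 9)), f"m{k}")
                      for k in range(n_motifs)]
            mode = "homotypic" if n_motifs == 1 else "heterotypic_or"
            model = ClusterModel(motifs=motifs, mode=mode,
                                 gap_penalty_bits_per_base=float(rng.uniform(0, 0.4)))
            seq = random_sequence(rng, int(rng.integers(10, 61)))
            expected = chain_cluster_score(model, uniform_bg, seq)
            got = cluster_score(model, uniform_bg, seq)
            assert got.score_bits == pytest.approx(expected, abs=1e-9)

    def test_chain_oracle_agrees_with_subset_enumeration_on_tiny_cases(
        self, uniform_bg, rng
    ):
        checked = 0
        while checked < 15:
            motifs = [random_motif(rng, int(rng.integers(4, 9)))]
            model = ClusterModel(motifs=motifs)
            seq = random_sequence(rng, 25)
            from .oracles import candidate_sites

            if len(candidate_sites(model, uniform_bg, seq)) > 10:
                continue
            assert chain_cluster_score(model, uniform_bg, seq) == pytest.approx(
                subset_cluster_score(model, uniform_bg, seq), abs=1e-12
            )
            checked += 1

    def test_batch_kernel_matches_traceback_implementation(self, uniform_bg, rng):
        pwm = random_motif(rng, 6)
        model = ClusterModel(motifs=[pwm])
        seqs = [random_sequence(rng, 120) for _ in range(25)]
        batch = cluster_scores_batch(model, uniform_bg, seqs)
        detailed = [cluster_score(model, uniform_bg, s).score_bits for s in seqs]
        np.testing.assert_allclose(batch, detailed, atol=1e-9)

    def test_score_at_least_best_single_site_and_nonnegative(self, uniform_bg, rng):
        pwm = random_motif(rng, 5)
        model = ClusterModel(motifs=[pwm])
        for _ in range(20):
            seq = random_sequence(rng, 80)
            best_site = max(
                [s.score_bits for s in scan_sites(pwm, uniform_bg, seq, threshold_bits=0.0)],
                default=0.0,
            )
            rs = cluster_score(model, uniform_bg, seq)
            assert rs.score_bits >= best_site - 1e-9
            assert rs.score_bits >= 0.0

    def test_appending_sequence_never_decreases_score(self, uniform_bg, rng):
        pwm = random_motif(rng, 5)
        model = ClusterModel(motifs=[pwm])
        seq = random_sequence(rng, 60)
        base = cluster_score(model, uniform_bg, seq).score_bits
        for _ in range(10):
            seq = seq + random_sequence(rng, 10)
            new = cluster_score(model, uniform_bg, seq).score_bits
            assert new >= base - 1e-9
            base = new

    def test_strand_invariance(self, uniform_bg, rng):
        pwm = random_motif(rng, 6)
        model = ClusterModel(motifs=[pwm])
        for _ in range(20):
            seq = random_sequence(rng, 100)
            fwd = cluster_score(model, uniform_bg, seq).score_bits
            rev = cluster_score(model, uniform_bg, reverse_complement(seq)).score_bits
            assert fwd == pytest.approx(rev, abs=1e-9)

    def test_sites_used_are_nonoverlapping_and_inside_window(self, uniform_bg, rng):
        from crmrank.simulate import implant_pwm

        pwm = implant_pwm()
        seq = ("T" * 10 + pwm.consensus()) * 3 + "T" * 10
        rs = cluster_score(ClusterModel(motifs=[pwm]), uniform_bg, seq)
        spans = sorted((s.offset, s.offset + pwm.length) for s in rs.sites_used)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        lo, hi = rs.best_window
        assert all(lo <= s and e <= hi for s, e in spans)


class TestExports:
    def test_sites_roundtrip_through_gff3(self, uniform_bg):
        from crmrank.scoring import sites_to_gff3
        from crmrank.simulate import implant_pwm

        pwm = implant_pwm()
        seq = "T" * 15 + pwm.consensus() + "T" * 15
        sites = scan_sites(pwm, uniform_bg, seq, region_id="rX")
        text = sites_to_gff3(sites, {pwm.motif_id: pwm.length})
        rows = [ln.split("\t") for ln in text.splitlines() if not ln.startswith("#")]
        assert len(rows) == len(sites) == 1
        chrom, _, ftype, start, end, score, strand, _, attrs = rows[0]
        assert chrom == "rX" and ftype == "TF_binding_site"
        assert int(start) == sites[0].offset + 1
        assert int(end) - int(start) + 1 == pwm.length
        assert float(score) == pytest.approx(sites[0].score_bits, abs=1e-4)
        assert pwm.motif_id in attrs

    def test_region_score_tsv_layout(self, uniform_bg):
        from crmrank.scoring import region_scores_to_tsv
        from crmrank.simulate import implant_pwm

        pwm = implant_pwm()
        model = ClusterModel(motifs=[pwm])
        rs = cluster_score(model, uniform_bg, "T" * 10 + pwm.consensus() + "T" * 10, "rY")
        text = region_scores_to_tsv([rs])
        header, row = text.splitlines()
        assert header.split("\t")[0] == "region_id"
        fields = row.split("\t")
        assert fields[0] == "rY"
        assert float(fields[3]) == pytest.approx(rs.score_bits, abs=1e-4)


class TestHeterotypic:
    def _two_motif_model(self, mode):
        a = Pwm.from_counts("mA", np.array([[30.0, 0, 0, 0]] * 4))
        b = Pwm.from_counts("mB", np.array([[0.0, 30, 0, 0]] * 4))
        return ClusterModel(motifs=[a, b], mode=mode)

    def test_and_zeroes_single_motif_regions(self, uniform_bg):
        model = self._two_motif_model("heterotypic_and")
        only_a = cluster_score(model, uniform_bg, "GT" * 5 + "AAAA" + "GT" * 5, "rA")
        both = cluster_score(model, uniform_bg, "AAAA" + "GT" + "CCCC", "rB")
        filtered = heterotypic_filter([only_a, both], model)
        assert filtered[0].score_bits == 0.0
        assert filtered[1].score_bits == both.score_bits

    def test_or_passes_through(self, uniform_bg):
        model = self._two_motif_model("heterotypic_or")
        rs = cluster_score(model, uniform_bg, "AAAAGGCCCC")
        out = heterotypic_filter([rs], model)
        assert out[0].score_bits == rs.score_bits

    def test_homotypic_model_rejected(self, uniform_bg):
        model = ClusterModel(motifs=[_single_base_pwm()])
        with pytest.raises(ValueError):
            heterotypic_filter([], model)

    def test_mode_arity_validation(self):
        with pytest.raises(ValueError):
            ClusterModel(motifs=[_single_base_pwm()], mode="heterotypic_and")
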