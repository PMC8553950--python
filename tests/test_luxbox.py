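import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_region
from luxscreen.formats_io import Contig, OrfRecord
from luxscreen.luxbox import (
    MotifModel,
    RegulonConfig,
    build_motif,
    classify_hit_location,
    distance_upstream,
    extract_upstream,
    find_promoter_elements,
    find_shine_dalgarno,
    motif_score_pvalue,
    palindrome_mismatches,
    predict_regulon,
    revcomp,
    scan_region,
    score_site,
    write_meme_minimal,
)
from luxscreen.synthetic_data import DEFAULT_CONSENSUS, generate_motif_library

dna = st.text(alphabet="ACGT", min_size=2, max_size=30).filter(lambda s: len(s) % 2 == 0)


def random_model(rng, width=None):
    w = width or int(rng.integers(1, 7))
    n = int(rng.integers(2, 30))
    counts = rng.multinomial(n, rng.dirichlet(np.ones(4)), size=w)
    bg = rng.dirichlet(np.ones(4) * 5)
    return MotifModel(counts=counts, pseudocount=0.1, background=bg / bg.sum())


class TestBuildMotif:
    def test_log_odds_closed_form(self):
        m = build_motif(["AA", "AA"], pseudocount=0.25)
        # (2 + 0.25) / (2 + 1) / 0.25 = 3.0
        assert m.log_odds[0][0] == pytest.approx(math.log2(3.0))
        assert m.log_odds[1][0] == pytest.approx(math.log2(3.0))

    def test_counts_tally_per_column(self):
        m = build_motif(["AC", "GT"])
        assert m.counts[0].tolist() == [1, 0, 1, 0]  # A,G in column 1
        assert m.counts[1].tolist() == [0, 1, 0, 1]  # C,T in column 2

    def test_library_roundtrip_consensus(self):
        lib = generate_motif_library(mutation_rate=0.0, seed=3)
        m = build_motif(lib)
        assert m.consensus() == DEFAULT_CONSENSUS

    def test_training_rejects_ambiguity_and_zero_background(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            build_motif(["AN", "AA"])
        with pytest.raises(ValueError, match="background"):
            build_motif(["AA", "AA"], background=[0.5, 0.5, 0.0, 0.0])

    def test_meme_minimal_serialization(self, model, tmp_path):
        path = tmp_path / "motif.meme"
        write_meme_minimal(model, path)
        text = path.read_text()
        assert "letter-probability matrix" in text and "w= 20" in text


class TestScore:
    def test_score_from_worked_log_odds(self):
        m = build_motif(["AA", "AA"], pseudocount=0.25)
        assert score_site(m, "AA") == pytest.approx(2 * math.log2(3.0))

    def test_n_scores_zero(self):
        m = build_motif(["AA", "AA"], pseudocount=0.25)
        assert score_site(m, "NN") == 0.0

    def test_score_is_positionwise_sum(self):
        rng = np.random.default_rng(4)
        m = random_model(rng, width=4)
        site = "ACGT"
        expected = sum(m.log_odds[i]["ACGT".index(b)] for i, b in enumerate(site))
        assert score_site(m, site) == pytest.approx(expected)

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="width"):
            score_site(model, "ACGT")


class TestPvalue:
    def test_width_one_uniform_best_base(self):
        m = MotifModel(
            counts=np.array([[5, 1, 1, 1]]), pseudocount=0.1,
            background=np.full(4, 0.25),
        )
        best = float(m.log_odds[0].max())
        assert motif_score_pvalue(m, best) == pytest.approx(0.25)

    def test_minimum_score_has_total_mass(self, model):
        min_total = float(model.log_odds.min(axis=1).sum())
        assert motif_score_pvalue(model, min_total) == 1.0

    def test_above_maximum_returns_positive_mass(self, model):
        max_total = float(model.log_odds.max(axis=1).sum())
        p = motif_score_pvalue(model, max_total + 100.0)
        assert 0 < p <= motif_score_pvalue(model, max_total)

    def test_dp_equals_exhaustive_enumeration(self):
        """Convolution DP vs brute force over all 4^w sequences, w <= 5."""
        rng = np.random.default_rng(12)
        for _ in range(8):
            m = random_model(rng)
            ints, eps, min_total = m.integer_scores(1000)
            table = [
                (sum(int(ints[i, b]) for i, b in enumerate(seq)),
                 math.prod(float(m.background[b]) for b in seq))
                for seq in itertools.product(range(4), repeat=m.width)
            ]
            max_t = max(s for s, _ in table)
            for t in {1, max_t // 3, max_t}:
                oracle = math.fsum(p for s, p in table if s >= t)
                dp = motif_score_pvalue(m, min_total + t * eps)
                assert dp == pytest.approx(oracle, abs=1e-9)

    def test_pvalue_monotone_nonincreasing_in_score(self, model):
        scores = np.linspace(
            float(model.log_odds.min(axis=1).sum()),
            float(model.log_odds.max(axis=1).sum()),
            40,
        )
        ps = [motif_score_pvalue(model, s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestUpstream:
    contig = Contig("c1", "ACGT" * 200)  # 800 bp

    def test_plus_strand_window_arithmetic(self):
        orf = OrfRecord("o", "c1", 500, 700, "+")
        r = extract_upstream(orf, self.contig)
        assert (r.genomic_start, r.genomic_end, len(r)) == (100, 499, 400)
        assert r.sequence == self.contig.sequence[99:499]

    def test_plus_strand_clipped_at_contig_start(self):
        orf = OrfRecord("o", "c1", 200, 300, "+")
        r = extract_upstream(orf, self.contig)
        assert (r.genomic_start, r.genomic_end, r.clipped) == (1, 199, True)

    def test_minus_strand_reverse_complemented(self):
        contig = Contig("c1", "ACGT" * 150)  # 600 bp
        orf = OrfRecord("o", "c1", 50, 100, "-")
        r = extract_upstream(orf, contig)
        assert (r.genomic_start, r.genomic_end) == (101, 500)
        assert r.sequence == revcomp(contig.sequence[100:500])

    def test_flush_orf_yields_empty_clipped_region(self):
        orf = OrfRecord("o", "c1", 1, 90, "+")
        r = extract_upstream(orf, self.contig)
        assert len(r) == 0 and r.clipped

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_offset_roundtrip_reslices_site(self, strand):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
        contig = Contig("c1", seq)
        orf = (
            OrfRecord("o", "c1", 600, 900, "+")
            if strand == "+"
            else OrfRecord("o", "c1", 100, 400, "-")
        )
        r = extract_upstream(orf, contig)
        for offset in (1, 17, len(r) - 19):
            g1, g2 = r.genomic_interval(offset, 20)
            genomic = seq[g1 - 1 : g2]
            observed = r.sequence[offset - 1 : offset + 19]
            assert observed == (genomic if strand == "+" else revcomp(genomic))


class TestPalindrome:
    def test_printed_lux_boxes(self):
        assert palindrome_mismatches("ACCTGGCGGTTCCGCCAGGT") == 2
        assert palindrome_mismatches("CACTGGACGAGTGTACAGTT") == 8

    def test_perfect_palindrome(self):
        assert palindrome_mismatches("ACGT") == 0

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            palindrome_mismatches("ACG")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(site=dna)
    def test_even_and_revcomp_invariant(self, site):
        mm = palindrome_mismatches(site)
        assert mm % 2 == 0
        assert mm == palindrome_mismatches(revcomp(site))
        # positionwise oracle
        rc = revcomp(site)
        assert mm == sum(a != b for a, b in zip(site, rc))


class TestScan:
    def _planted_region(self, seed=1, strand="+"):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        site = DEFAULT_CONSENSUS if strand == "+" else revcomp(DEFAULT_CONSENSUS)
        offset = 150
        return make_region(seq[: offset - 1] + site + seq[offset + 19 :]), offset

    def test_planted_consensus_found_at_its_offset(self, model):
        region, offset = self._planted_region(seed=1)
        hits = scan_region(model, region)
        assert [h.offset for h in hits] == [offset]
        assert hits[0].site == DEFAULT_CONSENSUS

    def test_opposite_strand_plant_reported_identically(self, model):
        fwd, offset = self._planted_region(seed=1, strand="+")
        rev, _ = self._planted_region(seed=1, strand="-")
        h_f = scan_region(model, fwd)[0]
        h_r = scan_region(model, rev)[0]
        assert h_f.offset == h_r.offset == offset
        assert h_f.site == h_r.site == DEFAULT_CONSENSUS
        assert {h_f.strand_within_region, h_r.strand_within_region} == {"+", "-"}

    def test_poly_a_region_has_no_hits_against_gc_model(self, model):
        region = make_region("A" * 400)
        # the model is GC-rich: the best poly-A window is far below threshold
        assert scan_region(model, region, background="model") == []

    def test_revcomp_region_mirrors_offsets(self, model):
        region, offset = self._planted_region(seed=5)
        mirrored = make_region(revcomp(region.sequence))
        h1 = {(h.offset, h.site)
              for h in scan_region(model, region, background="model")}
        h2 = {(len(region) - h.offset - 18, h.site)
              for h in scan_region(model, mirrored, background="model")}
        assert h1 == h2

    def test_short_region_warns_and_returns_empty(self, model):
        assert scan_region(model, make_region("ACGT", clipped=True)) == []


class TestLocationAndDistance:
    def test_distance_of_planted_site(self):
        # site ending 81 bp before the start codon
        region = make_region("A" * 400)
        from luxscreen.luxbox import MotifHit

        offset = 400 - 81 - 20 + 1
        hit = MotifHit(region, offset, "+", "G" * 20, 0.0, 1e-5, 2)
        assert distance_upstream(hit) == 81

    def test_intergenic_vs_intragenic_boundary(self):
        seq_region = make_region("A" * 400)
        from luxscreen.luxbox import MotifHit

        hit = MotifHit(seq_region, 100, "+", "G" * 20, 0.0, 1e-5, 2)
        g1, g2 = seq_region.genomic_interval(100, 20)  # 100..119
        clear = [OrfRecord("o1", "r1", 200, 300, "+")]
        touching = [OrfRecord("o1", "r1", g2, g2 + 50, "+")]  # 1 bp overlap
        assert classify_hit_location(hit, clear)[0] == "intergenic"
        assert classify_hit_location(hit, touching)[0] == "intragenic"


class TestPromoterElements:
    def _region_with(self, insert, tail_len=0):
        # site occupies positions 1-20; insert follows immediately
        filler = "C" * (120 - 20 - len(insert) - tail_len)
        return make_region("G" * 20 + insert + filler + "C" * tail_len)

    def test_exact_pair_with_17bp_spacer(self):
        region = self._region_with("TTGACA" + "C" * 17 + "TATAAT")
        pe = find_promoter_elements(region, 1, 20)
        assert pe.paired and pe.spacer == 17
        assert pe.minus35_found and pe.minus10_found
        assert pe.minus35_position == 21

    def test_long_spacer_rejected_elements_unpaired(self):
        region = self._region_with("TTGACA" + "C" * 25 + "TATAAT")
        pe = find_promoter_elements(region, 1, 20, mismatch_max=0)
        assert not pe.paired
        assert pe.minus35_found and pe.minus10_found

    def test_one_mismatch_minus10_found(self):
        region = self._region_with("AAAAAA" + "C" * 10 + "TATACT", tail_len=4)
        pe = find_promoter_elements(region, 1, 20, mismatch_max=1)
        assert pe.minus10_found

    def test_nothing_upstream_of_site_is_searched(self):
        region = make_region("TTGACA" + "C" * 17 + "TATAAT" + "G" * 40)
        pe = find_promoter_elements(region, len(region) - 19, 20, mismatch_max=0)
        assert not (pe.minus35_found or pe.minus10_found)


class TestShineDalgarno:
    def test_exact_core_at_spacing_seven(self):
        region = make_region("C" * 367 + "AGGAGG" + "C" * 7)
        found, pos = find_shine_dalgarno(region)
        assert found and pos == 368

    def test_no_purine_rich_window(self):
        assert find_shine_dalgarno(make_region("C" * 400))[0] is False

    def test_partial_core_run_of_four(self):
        # GGAG matches core positions 2-5 consecutively
        region = make_region("C" * 388 + "GGAG" + "C" * 8)
        assert find_shine_dalgarno(region)[0] is True

    def test_spacing_out_of_range_not_called(self):
        region = make_region("C" * 380 + "AGGAGG" + "C" * 16)  # 16 nt > 14
        assert find_shine_dalgarno(region)[0] is False


class TestPredictRegulon:
    def _divergent_setup(self, site):
        # receptor(-) .. [d_rec=125 | site 20bp | d_syn=81] .. synthase(+)
        rng = np.random.default_rng(21)
        rec = OrfRecord("rec", "c1", 301, 900, "-")
        gap = 125 + 20 + 81
        syn = OrfRecord("syn", "c1", 901 + gap, 1700 + gap, "+")
        length = syn.end + 300
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=length)))
        g1 = syn.start - 81 - 20
        seq[g1 - 1 : g1 + 19] = list(site)
        return [Contig("c1", "".join(seq))], [rec, syn], g1

    def test_divergent_pair_shares_one_genomic_site(self, model):
        contigs, orfs, g1 = self._divergent_setup(DEFAULT_CONSENSUS)
        out = predict_regulon(contigs, orfs, model)
        assert len(out) == 2
        by_orf = {c.orf_id: c for c in out}
        assert by_orf["syn"].distance_upstream == 81
        assert by_orf["rec"].distance_upstream == 125
        assert by_orf["syn"].genomic_start == by_orf["rec"].genomic_start == g1
        assert by_orf["syn"].shared_bidirectional_with == "rec"
        assert by_orf["rec"].shared_bidirectional_with == "syn"
        assert all(c.location_class == "intergenic" for c in out)

    def test_weak_site_below_threshold_yields_nothing(self, model):
        # accumulate mutations until the site's p-value crosses the threshold
        site = DEFAULT_CONSENSUS
        p = motif_score_pvalue(model, score_site(model, site))
        for pos in range(20):
            site = site[:pos] + ("A" if site[pos] != "A" else "C") + site[pos + 1:]
            p = motif_score_pvalue(model, score_site(model, site))
            if p >= 1e-4:
                break
        assert 1e-4 <= p < 1e-1
        contigs, orfs, _ = self._divergent_setup(site)
        out = predict_regulon(
            contigs, orfs, model, RegulonConfig(background="model")
        )
        assert out == []

    def test_target_restriction_skips_other_contigs(self, model):
        contigs, orfs, _ = self._divergent_setup(DEFAULT_CONSENSUS)
        assert predict_regulon(contigs, orfs, model, target_contig_ids=[]) == []

    def test_ranked_by_pvalue(self, model):
        contigs, orfs, _ = self._divergent_setup(DEFAULT_CONSENSUS)
        out = predict_regulon(contigs, orfs, model)
        ps = [c.hit.p_value for c in out]
        assert ps == sorted(ps)
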