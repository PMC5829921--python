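"""Spectrum classification, normalization, comparison and refitting tests."""

import numpy as np
import pytest
from scipy import stats

from mutaflux.contexts import (
    CONTEXT_INDEX_96,
    CONTEXT_LABELS_96,
    TRINUC_INDEX_32,
    TRINUC_LABELS_32,
    revcomp,
    trinucleotide_census,
)
from mutaflux.spectrum import (
    ReferenceMismatchError,
    SignatureCatalog,
    SpectrumProfile,
    build_spectrum,
    chisq_yates,
    classify_substitution,
    cosine_similarity,
    normalize_by_opportunity,
    refit_signatures,
)
from mutaflux.synthetic_data import SimulationConfig, simulate_catalog, simulate_genome

from conftest import make_variant


class TestClassify:
    def test_pyrimidine_reference_passthrough(self):
        assert classify_substitution("C", "A", "T", "T") == ("C>A", "T[C>A]T")

    def test_purine_reference_reverse_complemented(self):
        assert classify_substitution("G", "T", "A", "A") == ("C>A", "T[C>A]T")

    def test_one_record_per_class(self):
        cases = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
        counts = np.zeros(96)
        for ref, alt in cases:
            _, label = classify_substitution(ref, alt, "A", "A")
            counts[CONTEXT_INDEX_96[label]] += 1
        profile = SpectrumProfile("six", counts)
        assert profile.counts6.tolist() == [1, 1, 1, 1, 1, 1]

    def test_ambiguous_base_rejected(self):
        from mutaflux.contexts import AmbiguousBaseError

        with pytest.raises(AmbiguousBaseError):
            classify_substitution("N", "A", "C", "C")


class TestBuildSpectrum:
    def test_empty_records_zero_profile(self):
        profile = build_spectrum([], {"chr1": "ACGT"})
        assert profile.total == 0

    def test_single_bin_round_trip(self):
        seq = "ATCTA"  # TCT at positions 2-4 (1-based center 3)
        rec = make_variant(3, ref="C", alt="A")
        profile = build_spectrum([rec], {"chr1": seq})
        assert profile.counts96[CONTEXT_INDEX_96["T[C>A]T"]] == 1
        assert profile.total == 1

    def test_reference_mismatch_raises(self):
        rec = make_variant(3, ref="G", alt="T")
        with pytest.raises(ReferenceMismatchError):
            build_spectrum([rec], {"chr1": "ATCTA"})

    def test_end_positions_skipped_with_tally(self):
        seq = "CCCCC"
        recs = [make_variant(1, ref="C", alt="A"), make_variant(5, ref="C", alt="A"),
                make_variant(3, ref="C", alt="A")]
        profile = build_spectrum(recs, {"chr1": seq})
        assert profile.total == 1
        assert profile.n_skipped == 2

    def test_count_conservation(self):
        """classified + skipped = input records."""
        seq = "NCANTCTG"
        recs = [make_variant(2, ref="C", alt="A"),  # N flank -> skipped
                make_variant(6, ref="C", alt="T")]
        profile = build_spectrum(recs, {"chr1": seq})
        assert profile.total + profile.n_skipped == len(recs)

    def test_strand_invariance(self, signature_catalog):
        """A catalog and its full reverse complement give identical spectra."""
        cfg = SimulationConfig(seed=3, genome_length=30_000,
                               n_mutations=300,
                               signature_mix={"POLE_like": 0.5, "Flat": 0.5})
        seq, _ = simulate_genome(cfg)
        novel, _ = simulate_catalog(cfg, seq, signature_catalog)
        fwd = build_spectrum(novel, {"chrS": seq})
        rc_seq = revcomp(seq)
        n = len(seq)
        rc_records = [
            make_variant(
                n - r.pos + 1,
                ref=revcomp(r.ref_base),
                alt=revcomp(r.alt_base),
                chrom="chrS",
            )
            for r in novel
        ]
        rev = build_spectrum(rc_records, {"chrS": rc_seq})
        assert np.array_equal(fwd.counts96, rev.counts96)

    def test_multinomial_sampling_statistics(self, signature_catalog):
        """1,000 draws from a stated mixture stay within 3 SD per bin."""
        mix = {"POLE_like": 0.6, "MMR_like": 0.4}
        cfg = SimulationConfig(seed=4, genome_length=120_000, n_mutations=1000,
                               signature_mix=mix)
        seq, _ = simulate_genome(cfg)
        novel, _ = simulate_catalog(cfg, seq, signature_catalog)
        profile = build_spectrum(novel, {"chrS": seq})
        expected = 1000 * (
            0.6 * signature_catalog.vector("POLE_like")
            + 0.4 * signature_catalog.vector("MMR_like")
        )
        sd = np.sqrt(expected * (1 - expected / 1000))
        # allow 3 SD with a floor for near-empty bins
        assert (np.abs(profile.counts96 - expected) <= 3 * sd + 3).all()


class TestOpportunity:
    def test_census_matches_brute_force(self):
        cfg = SimulationConfig(seed=5, genome_length=5000)
        seq, census = simulate_genome(cfg)
        brute = np.zeros(32, dtype=int)
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            canon = tri if tri[1] in "CT" else revcomp(tri)
            brute[TRINUC_INDEX_32[canon]] += 1
        assert np.array_equal(census, brute)
        assert np.array_equal(trinucleotide_census(seq), brute)

    def test_uniform_census_preserves_proportions(self):
        counts = np.zeros(96)
        counts[[0, 20, 50]] = [10, 30, 60]
        profile = SpectrumProfile("s", counts, opportunity=np.full(32, 100.0))
        normalized = normalize_by_opportunity(profile)
        assert np.allclose(normalized.counts96, counts)

    def test_doubling_one_context_halves_its_share(self):
        counts = np.zeros(96)
        ctx_a = CONTEXT_INDEX_96["A[C>A]A"]  # trinuc ACA
        ctx_b = CONTEXT_INDEX_96["T[C>A]T"]  # trinuc TCT
        counts[[ctx_a, ctx_b]] = [50, 50]
        opp = np.full(32, 100.0)
        opp[TRINUC_INDEX_32["ACA"]] = 200.0  # doubled census for ACA
        profile = SpectrumProfile("s", counts, opportunity=opp)
        normalized = normalize_by_opportunity(profile)
        # before rescale: 0.25 vs 0.5 -> after rescale shares are 1/3 and 2/3
        assert normalized.counts96[ctx_a] == pytest.approx(100 / 3)
        assert normalized.counts96[ctx_b] == pytest.approx(200 / 3)
        assert normalized.total == pytest.approx(100)

    def test_zero_opportunity_with_count_rejected(self):
        counts = np.zeros(96)
        counts[CONTEXT_INDEX_96["A[C>A]A"]] = 5
        opp = np.full(32, 10.0)
        opp[TRINUC_INDEX_32["ACA"]] = 0.0
        with pytest.raises(ValueError):
            normalize_by_opportunity(SpectrumProfile("s", counts, opportunity=opp))


def yates_2x2_oracle(a, b, c, d):
    """Textbook 2x2 Yates statistic: N(|ad-bc|-N/2)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


class TestChisqYates:
    def test_proportional_table_statistic_zero(self):
        stat, df, p = chisq_yates([10, 20], [20, 40])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_hand_evaluated_2x2(self):
        stat, df, p = chisq_yates([10, 20], [20, 10])
        assert stat == pytest.approx(5.4, abs=0.01)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_matches_oracle_on_random_2x2_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            stat, df, _ = chisq_yates([a, b], [c, d])
            assert stat == pytest.approx(yates_2x2_oracle(a, b, c, d), rel=1e-9)

    def test_correction_shrinks_statistic(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(1, 50, size=6)
            b = rng.integers(1, 50, size=6)
            stat, df, _ = chisq_yates(a, b)
            uncorrected = stats.chi2_contingency(np.vstack([a, b]), correction=False)[0]
            assert stat <= uncorrected + 1e-12

    def test_six_class_per_cell_correction(self):
        a = np.array([30, 5, 10, 5, 8, 2], dtype=float)
        b = np.array([10, 8, 12, 6, 7, 7], dtype=float)
        table = np.vstack([a, b])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = (np.maximum(np.abs(table - expected) - 0.5, 0) ** 2 / expected).sum()
        stat, df, _ = chisq_yates(a, b)
        assert stat == pytest.approx(oracle)
        assert df == 5

    def test_zero_total_category_dropped(self):
        stat, df, _ = chisq_yates([5, 0, 10, 3], [7, 0, 2, 9])
        assert df == 2  # one category dropped from a 2x4 table

    def test_all_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_yates([0, 0], [1, 2])


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        v = np.zeros(96)
        w = np.zeros(96)
        v[:48], w[48:] = 1, 1
        assert cosine_similarity(v, w) == 0.0

    def test_equal_mixture_of_orthogonal_signatures(self):
        s1, s2 = np.zeros(96), np.zeros(96)
        s1[:10] = 0.1
        s2[50:60] = 0.1
        v = 0.5 * s1 + 0.5 * s2
        assert cosine_similarity(v, s1) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestRefit:
    def test_exact_catalog_member_recovered(self, signature_catalog):
        profile = SpectrumProfile(
            "pure", 1000 * signature_catalog.vector("POLE_like")
        )
        result = refit_signatures(profile, signature_catalog)
        assert result.contributions["POLE_like"] == pytest.approx(1.0, abs=1e-6)
        assert result.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_profile_gets_zero_weights(self):
        # catalog concentrated on first bins; profile on the last ones
        vec = np.zeros(96)
        vec[:4] = 0.25
        catalog = SignatureCatalog(names=["s1"], vectors=vec[None, :])
        counts = np.zeros(96)
        counts[-4:] = 25
        result = refit_signatures(SpectrumProfile("orth", counts), catalog)
        assert result.weights.sum() == pytest.approx(0.0, abs=1e-12)
        profile_norm = np.linalg.norm(counts / counts.sum())
        assert result.residual_norm == pytest.approx(profile_norm)

    def test_two_signature_mixture_recovery(self, signature_catalog):
        """0.7/0.3 mixture at 10,000 mutations recovered within 0.05."""
        mix = 0.7 * signature_catalog.vector("POLE_like") + 0.3 * signature_catalog.vector(
            "APOBEC_like"
        )
        rng = np.random.default_rng(11)
        counts = rng.multinomial(10_000, mix).astype(float)
        result = refit_signatures(SpectrumProfile("mix", counts), signature_catalog)
        assert result.contributions["POLE_like"] == pytest.approx(0.7, abs=0.05)
        assert result.contributions["APOBEC_like"] == pytest.approx(0.3, abs=0.05)

    def test_empty_catalog_rejected(self, signature_catalog):
        empty = SignatureCatalog(names=[], vectors=np.zeros((0, 96)))
        with pytest.raises(ValueError):
            refit_signatures(SpectrumProfile("s", np.ones(96)), empty)

    def test_catalog_tsv_round_trip(self, tmp_path, signature_catalog):
        path = tmp_path / "sigs.tsv"
        signature_catalog.to_tsv(path)
        back = SignatureCatalog.from_tsv(path)
        assert back.names == signature_catalog.names
        assert np.allclose(back.vectors, signature_catalog.vectors)
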