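import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcontext import (
    ALL_HEXAMERS,
    ContextPreferenceModel,
    HexamerProfile,
    build_observed_profile,
    extract_context,
    preference_correlation,
    rank_profile,
    read_preference_table,
    revcomp_hexamer,
    symmetrize_profile,
)
from methcontext.context import contexts_for_records, correlation_matrix, hexamer_pairs
from methcontext.errors import (
    FormatError,
    InsufficientDataError,
    PatternError,
    UndefinedStatisticError,
)
from methcontext.simulate import SimConfig, simulate_genome, simulate_methylome, simulate_preference_profile

# independent reverse-complement oracle for the tests
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s):
    return "".join(_COMP[b] for b in reversed(s))


def _profile(values, name="p"):
    return HexamerProfile(name, pd.Series(values, index=list(ALL_HEXAMERS)))


class TestRevcompHexamer:
    def test_palindrome_fixed(self):
        assert revcomp_hexamer("AACGTT") == "AACGTT"

    def test_forced_by_complementarity(self):
        assert revcomp_hexamer("AACGCC") == "GGCGTT"

    def test_involution_over_all_256(self):
        for h in ALL_HEXAMERS:
            assert revcomp_hexamer(revcomp_hexamer(h)) == h
            assert revcomp_hexamer(h) == _rc(h)

    @pytest.mark.parametrize("bad", ["AACTAA", "ACG", "AACGNZ", "aacgtt"])
    def test_invalid_hexamer_rejected(self, bad):
        with pytest.raises(PatternError):
            revcomp_hexamer(bad)

    def test_partition_into_pairs_and_palindromes(self):
        pairs, palindromes = hexamer_pairs()
        assert len(pairs) == 120 and len(palindromes) == 16
        flat = {h for p in pairs for h in p} | set(palindromes)
        assert flat == set(ALL_HEXAMERS)
        assert all(_rc(h) == h for h in palindromes)


class TestExtractContext:
    # tiny_genome c1 = TTACGGTT: CpG with C at 1-based 4, G at 5

    def test_plus_strand_readoff(self, tiny_genome):
        assert extract_context(tiny_genome, "c1", 4, "+") == "TACGGT"

    def test_minus_strand_is_revcomp_of_plus(self, tiny_genome):
        assert extract_context(tiny_genome, "c1", 5, "-") == _rc("TACGGT")

    def test_window_underflow_returns_none(self, tiny_genome):
        assert extract_context(tiny_genome, "c1", 2, "+") is None

    def test_non_cpg_site_returns_none(self, tiny_genome):
        assert extract_context(tiny_genome, "c1", 3, "+") is None

    def test_out_of_contig_position_raises(self, tiny_genome):
        with pytest.raises(FormatError):
            extract_context(tiny_genome, "c1", 99, "+")

    def test_window_with_n_returns_none(self):
        from methcontext import GenomeSequence

        g = GenomeSequence({"c1": "TNACGGTT"})
        assert extract_context(g, "c1", 4, "+") is None

    def test_minus_equals_revcomp_of_plus_genomewide(self, sim_bundle):
        """Strand consistency, exhaustive over a simulated genome."""
        genome = sim_bundle["genome"]
        seq = genome["chr1"]
        cpg = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        checked = 0
        for p in cpg:
            plus = extract_context(genome, "chr1", p + 1, "+")
            minus = extract_context(genome, "chr1", p + 2, "-")
            if plus is None:
                assert minus is None or p < 3
                continue
            assert minus == _rc(plus)
            checked += 1
        assert checked > 1000

    def test_vectorized_matches_scalar(self, sim_bundle):
        genome = sim_bundle["genome"]
        seq = genome["chr2"]
        cpg = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"][:500]
        records = pd.DataFrame(
            {"contig": "chr2",
             "pos": [p + 1 for p in cpg] + [p + 2 for p in cpg],
             "strand": ["+"] * len(cpg) + ["-"] * len(cpg)}
        )
        idx = contexts_for_records(genome, records)
        for i in range(len(records)):
            scalar = extract_context(genome, "chr2", int(records.pos[i]), records.strand[i])
            vector = ALL_HEXAMERS[idx[i]] if idx[i] >= 0 else None
            assert scalar == vector


class TestObservedProfile:
    def test_unweighted_mean_of_site_levels(self, methylome_factory):
        from methcontext import GenomeSequence

        g = GenomeSequence({"c1": "TTACGGTTACGGTT"})  # CpGs at 4-5 and 10-11, same context
        m = methylome_factory([("c1", 4, "+", 2, 8), ("c1", 10, "+", 8, 2)])
        prof = build_observed_profile(m, g, min_coverage=10)
        assert prof.values["TACGGT"] == pytest.approx(0.5)
        assert prof.n_sites["TACGGT"] == 2

    def test_low_coverage_site_contributes_nothing(self, methylome_factory):
        from methcontext import GenomeSequence

        g = GenomeSequence({"c1": "TTACGGTT"})
        m = methylome_factory([("c1", 4, "+", 5, 4)])
        prof = build_observed_profile(m, g, min_coverage=10)
        assert np.isnan(prof.values["TACGGT"]) and prof.n_observed == 0

    def test_constant_methylome_recovers_constant(self, sim_bundle):
        """All-zero weights at alpha0=logit(0.7): every context mean ~0.7."""
        config = SimConfig(seed=21, genome_length=150_000, n_contigs=1, cgi_count=0,
                           enzyme_weights={"E": 0.0}, baseline=np.log(0.7 / 0.3),
                           site_noise_sd=0.0, coverage_mean=50.0,
                           depletion_factors={"t": {}}, coupled_timepoints=())
        genome, cgis = simulate_genome(config)
        prof_e = simulate_preference_profile(1, name="E")
        meth = simulate_methylome(genome, cgis, {"E": prof_e}, config, "t")
        obs = build_observed_profile(meth, genome)
        vals = obs.values.dropna()
        assert len(vals) == 256  # coupon-collector: every context observed
        # binomial error: sd ~ sqrt(.21/50)/sqrt(n_sites) per context
        n = obs.n_sites[vals.index].to_numpy()
        assert np.all(np.abs(vals.to_numpy() - 0.7) < 6 * np.sqrt(0.21 / 50 / np.maximum(n, 1)) + 0.02)


class TestSymmetrize:
    def test_pairwise_mean(self):
        vals = pd.Series(0.0, index=list(ALL_HEXAMERS))
        vals["AACGCC"], vals["GGCGTT"] = 0.2, 0.6
        out = symmetrize_profile(HexamerProfile("p", vals))
        assert out.values["AACGCC"] == out.values["GGCGTT"] == pytest.approx(0.4)

    def test_palindrome_fixed_point_and_idempotence(self):
        rng = np.random.default_rng(0)
        prof = _profile(rng.random(256))
        once = symmetrize_profile(prof)
        twice = symmetrize_profile(once)
        pd.testing.assert_series_equal(once.values, twice.values)
        for h in (h for h in ALL_HEXAMERS if _rc(h) == h):
            assert once.values[h] == prof.values[h]
        # invariant under revcomp
        for h in ALL_HEXAMERS:
            assert once.values[h] == pytest.approx(once.values[_rc(h)])

    def test_missing_entries_rejected(self):
        vals = pd.Series(1.0, index=list(ALL_HEXAMERS))
        vals.iloc[0] = np.nan
        with pytest.raises(FormatError, match="missing"):
            symmetrize_profile(HexamerProfile("p", vals))


class TestRankProfile:
    def test_descending_with_average_ties(self):
        vals = pd.Series(0.0, index=list(ALL_HEXAMERS))
        vals[:] = np.nan
        vals["AACGAA"], vals["AACGAC"], vals["AACGAG"] = 2, 2, 1
        ranks = rank_profile(_profile(vals))
        assert ranks["AACGAA"] == ranks["AACGAC"] == 1.5
        assert ranks["AACGAG"] == 3.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random(256)
        r1 = rank_profile(_profile(vals))
        r2 = rank_profile(_profile(np.exp(3 * vals)))
        pd.testing.assert_series_equal(r1, r2)

    def test_too_few_entries_rejected(self):
        vals = pd.Series(np.nan, index=list(ALL_HEXAMERS))
        vals.iloc[0], vals.iloc[1] = 1, 2
        with pytest.raises(InsufficientDataError):
            rank_profile(_profile(vals))


class TestPreferenceCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        p = _profile(rng.random(256))
        assert preference_correlation(p, p).r == pytest.approx(1.0)

    def test_sign_flip(self):
        rng = np.random.default_rng(3)
        vals = rng.random(256)
        r = preference_correlation(_profile(vals), _profile(-vals)).r
        assert r == pytest.approx(-1.0)

    def test_zero_variance_raises_not_silent_zero(self):
        rng = np.random.default_rng(4)
        with pytest.raises(UndefinedStatisticError):
            preference_correlation(_profile(rng.random(256)), _profile(np.ones(256)))

    def test_missing_hexamers_dropped_pairwise(self):
        rng = np.random.default_rng(5)
        vals = rng.random(256)
        obs = vals.copy()
        obs[:100] = np.nan
        res = preference_correlation(_profile(obs), _profile(vals))
        assert res.n == 156

    def test_pearson_ranks_equals_independent_spearman(self):
        """1000 random profile pairs vs scipy's Spearman, to 1e-12."""
        rng = np.random.default_rng(6)
        for _ in range(1000):
            x, y = rng.random(256), rng.random(256)
            ours = preference_correlation(_profile(x), _profile(y), "pearson_ranks").r
            ref = stats.spearmanr(x, y).statistic
            assert abs(ours - ref) < 1e-12


class TestCorrelationMatrix:
    def test_cardinality_and_order(self, sim_bundle):
        config, genome = sim_bundle["config"], sim_bundle["genome"]
        profiles = sim_bundle["profiles"]
        samples = [
            simulate_methylome(genome, sim_bundle["cgis"], profiles, config, tp)
            for tp in ("day0", "day4_enzyme")
        ]
        table = correlation_matrix(samples, genome, list(profiles.values()))
        assert len(table) == 2 * 3
        assert list(table["sample_id"][:3]) == ["day0"] * 3

    def test_model_symmetrizes_named_enzymes(self, sim_bundle):
        config, genome = sim_bundle["config"], sim_bundle["genome"]
        profiles = sim_bundle["profiles"]
        samples = [simulate_methylome(genome, sim_bundle["cgis"], profiles, config, "day0")]
        model = ContextPreferenceModel(samples, genome, list(profiles.values()),
                                       symmetrize=("DNMT3A", "DNMT3B"))
        by_name = {e.name: e for e in model.enzymes}
        assert by_name["DNMT3A"].symmetrized and by_name["DNMT3B"].symmetrized
        assert not by_name["DNMT1"].symmetrized
        res = model.fit()
        assert set(res.table["enzyme"]) == {"DNMT1", "DNMT3A", "DNMT3B"}
        assert res.summary()


class TestPreferenceTableIO:
    def test_roundtrip_256_rows(self, tmp_path):
        prof = simulate_preference_profile(9, name="x")
        from methcontext.context import write_preference_table

        p = tmp_path / "pref.tsv"
        write_preference_table(prof, p)
        back = read_preference_table(p, name="x")
        pd.testing.assert_series_equal(prof.values, back.values)

    def test_missing_hexamer_named(self, tmp_path):
        lines = [f"{h}\t0.5" for h in ALL_HEXAMERS if h != "AACGAA"]
        p = tmp_path / "pref.tsv"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="AACGAA"):
            read_preference_table(p)

    def test_non_nncgnn_hexamer_rejected(self, tmp_path):
        p = tmp_path / "pref.tsv"
        p.write_text("AACTAA\t0.5\n")
        with pytest.raises(FormatError, match="NNCGNN"):
            read_preference_table(p)
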