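"""GY94 rate matrix, pruning likelihood, model fitting, LRTs and BH."""

import math

import numpy as np
import pytest

from wgdtrace._codons import get_code, is_transition
from wgdtrace.codonml import (
    CodonFrequencies,
    CodonModelSpec,
    LikelihoodEngine,
    bh_adjust,
    build_gy94_matrix,
    compute_tree_loglik,
    fit_codon_model,
    fit_model_series,
    likelihood_ratio_test,
    transition_matrix,
)
from wgdtrace.core_io import CodonAlignment, SequenceRecord, read_newick
from wgdtrace.simulate import simulate_codon_alignment

from _oracles import bh_oracle, exhaustive_4taxon_loglik

CODE = get_code(1)


class TestRateMatrix:
    def test_neighbor_rates_equal_under_neutral_uniform(self, uniform_freqs):
        Q = build_gy94_matrix(uniform_freqs.pi, kappa=1.0, omega=1.0,
                              scale=False)
        off = Q[Q > 0]
        assert np.allclose(off, off[0])

    def test_rows_sum_to_zero(self, uniform_freqs):
        Q = build_gy94_matrix(uniform_freqs.pi, 2.0, 0.3)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_multi_nucleotide_changes_forbidden(self, uniform_freqs):
        Q = build_gy94_matrix(uniform_freqs.pi, 2.0, 0.3, scale=False)
        for i, ci in enumerate(CODE.codons[:10]):
            for j, cj in enumerate(CODE.codons):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert Q[i, j] == 0.0

    def test_detailed_balance(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(CODE.n))
        Q = build_gy94_matrix(pi, kappa=3.0, omega=0.4)
        flux = pi[:, None] * Q
        idx = rng.integers(0, CODE.n, size=(100, 2))
        for i, j in idx:
            assert flux[i, j] == pytest.approx(flux[j, i], abs=1e-14)

    def test_kappa_and_omega_factors(self, uniform_freqs):
        kappa, omega = 2.5, 0.3
        Q = build_gy94_matrix(uniform_freqs.pi, kappa, omega, scale=False)
        i = CODE.index["TTT"]
        syn_ts = Q[i, CODE.index["TTC"]]      # synonymous transition
        nonsyn_tv = Q[i, CODE.index["TTA"]]   # nonsynonymous transversion
        base = uniform_freqs.pi[0]
        assert syn_ts == pytest.approx(base * kappa)
        assert nonsyn_tv == pytest.approx(base * omega)
        assert is_transition("T", "C") and not is_transition("T", "A")

    def test_transition_matrix_rows_sum_to_one_and_stationarity(self):
        rng = np.random.default_rng(8)
        pi = rng.dirichlet(np.ones(CODE.n) * 5)
        Q = build_gy94_matrix(pi, 2.0, 0.2)
        for t in rng.uniform(0, 5, size=5):
            P = transition_matrix(Q, pi, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(pi @ P, pi, atol=1e-9)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            build_gy94_matrix(np.ones(CODE.n), 2.0, 0.5)  # does not sum to 1


class TestLikelihood:
    def test_zero_branch_lengths_give_log_pi(self, uniform_freqs):
        aln = CodonAlignment([
            SequenceRecord("A", "ATG", "dna"),
            SequenceRecord("B", "ATG", "dna"),
        ])
        tree = read_newick("(A:0.0,B:0.0);")
        spec = CodonModelSpec.m0(2.0, 0.5, uniform_freqs)
        lnL = compute_tree_loglik(aln, tree, spec)
        assert lnL == pytest.approx(math.log(1.0 / CODE.n), abs=1e-10)

    def test_two_taxon_closed_form(self, uniform_freqs):
        tree = read_newick("(A:0.2,B:0.3);")
        spec = CodonModelSpec.m0(2.0, 0.5, uniform_freqs)
        aln, _ = simulate_codon_alignment(tree, spec, 40, seed=7)
        lnL = compute_tree_loglik(aln, tree, spec)
        Q = build_gy94_matrix(uniform_freqs.pi, 2.0, 0.5)
        P = transition_matrix(Q, uniform_freqs.pi, 0.5)  # t1 + t2
        pi = uniform_freqs.pi
        closed = sum(
            math.log(pi[CODE.index[ca]] * P[CODE.index[ca], CODE.index[cb]])
            for ca, cb in zip(aln.codons_of("A"), aln.codons_of("B"))
        )
        assert lnL == pytest.approx(closed, abs=1e-8)

    def test_four_taxon_exhaustive_state_sum(self, uniform_freqs):
        lengths = {"A": 0.15, "B": 0.25, "C": 0.1, "D": 0.3,
                   "internal": 0.2}
        # root sits on the A/B junction, matching the oracle's state sum
        tree = read_newick(
            f"(A:{lengths['A']},B:{lengths['B']},"
            f"(C:{lengths['C']},D:{lengths['D']}):{lengths['internal']});"
        )
        spec = CodonModelSpec.m0(1.8, 0.4, uniform_freqs)
        aln, _ = simulate_codon_alignment(tree, spec, 5, seed=21)
        lnL = compute_tree_loglik(aln, tree, spec)

        Q = build_gy94_matrix(uniform_freqs.pi, 1.8, 0.4)
        P = {
            k: transition_matrix(Q, uniform_freqs.pi, t)
            for k, t in lengths.items()
        }
        codons_by_leaf = {
            name: [CODE.index[c] for c in aln.codons_of(name)]
            for name in "ABCD"
        }
        oracle = exhaustive_4taxon_loglik(codons_by_leaf, None, P,
                                          uniform_freqs.pi)
        assert lnL == pytest.approx(oracle, abs=1e-8)

    def test_rerooting_invariance(self, uniform_freqs):
        spec = CodonModelSpec.m0(2.0, 0.3, uniform_freqs)
        t1 = read_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07);")
        # same unrooted tree, rooted along the central edge differently
        t2 = read_newick("(A:0.1,B:0.2,(C:0.15,D:0.1):0.12);")
        aln, _ = simulate_codon_alignment(t1, spec, 30, seed=5)
        assert compute_tree_loglik(aln, t1, spec) == pytest.approx(
            compute_tree_loglik(aln, t2, spec), abs=1e-8
        )

    def test_gap_codons_integrate_over_states(self, uniform_freqs):
        tree = read_newick("(A:0.1,B:0.1);")
        spec = CodonModelSpec.m0(2.0, 0.5, uniform_freqs)
        aln = CodonAlignment([
            SequenceRecord("A", "ATGAAA", "dna"),
            SequenceRecord("B", "ATG---", "dna"),
        ])
        lnL = compute_tree_loglik(aln, tree, spec)
        only_first = CodonAlignment([
            SequenceRecord("A", "ATG", "dna"),
            SequenceRecord("B", "ATG", "dna"),
        ])
        first = compute_tree_loglik(only_first, tree, spec)
        # gap column contributes exactly the marginal of A's codon
        assert lnL == pytest.approx(first + math.log(1 / CODE.n), abs=1e-9)

    def test_missing_leaf_sequence_rejected(self, uniform_freqs):
        aln = CodonAlignment([SequenceRecord("A", "ATG", "dna"),
                              SequenceRecord("B", "ATG", "dna")])
        tree = read_newick("(A:0.1,X:0.1);")
        with pytest.raises(ValueError, match="without sequence"):
            LikelihoodEngine(aln, tree)


class TestFitting:
    def test_m0_parameter_recovery(self, uniform_freqs):
        tree = read_newick(
            "(((a:0.1,b:0.15):0.1,(c:0.12,d:0.08):0.07):0.05,"
            "((e:0.1,f:0.2):0.06,(g:0.1,h:0.1):0.1):0.05);"
        )
        spec = CodonModelSpec.m0(2.0, 0.2, uniform_freqs)
        aln, _ = simulate_codon_alignment(tree, spec, 300, seed=42)
        fit = fit_codon_model(aln, tree, "M0", omega_starts=[0.5])
        assert fit.params["omega"] == pytest.approx(0.2, abs=0.05)
        assert fit.converged

    def test_branch2_nests_above_m0(self, tree6, uniform_freqs):
        spec = CodonModelSpec.m0(2.0, 0.2, uniform_freqs)
        aln, _ = simulate_codon_alignment(tree6, spec, 60, seed=9)
        fits = fit_model_series(aln, tree6, ["branch2"],
                                omega_starts=[0.3])
        assert fits["branch2"].lnL >= fits["M0"].lnL - 1e-6

    def test_per_start_record_kept(self, tree6, uniform_freqs):
        spec = CodonModelSpec.m0(2.0, 0.2, uniform_freqs)
        aln, _ = simulate_codon_alignment(tree6, spec, 40, seed=2)
        fit = fit_codon_model(aln, tree6, "M0", omega_starts=[0.05, 1.0])
        assert [s["omega_start"] for s in fit.starts] == [0.05, 1.0]
        assert fit.lnL == max(s["lnL"] for s in fit.starts)

    def test_foreground_required_for_branch_models(self, uniform_freqs):
        tree = read_newick("(a:0.1,b:0.1,(c:0.1,d:0.1):0.1);")
        aln, _ = simulate_codon_alignment(
            tree, CodonModelSpec.m0(2.0, 0.2, uniform_freqs), 10, seed=1
        )
        with pytest.raises(ValueError, match="foreground"):
            fit_codon_model(aln, tree, "branch2")
        with pytest.raises(ValueError, match="clade"):
            fit_codon_model(aln, tree, "CmC")

    def test_family_aliases_accepted(self, tree6, uniform_freqs):
        spec = CodonModelSpec.m0(2.0, 0.2, uniform_freqs)
        aln, _ = simulate_codon_alignment(tree6, spec, 20, seed=3)
        fit = fit_codon_model(aln, tree6, "m2a_ref", omega_starts=[0.5],
                              estimate_branch_lengths=False)
        assert fit.family == "M2a_rel"


class TestLRT:
    def _fake_fit(self, family, lnL, n_model):
        from wgdtrace.codonml import FitResult

        return FitResult(family=family, lnL=lnL, params={},
                         n_free_params=n_model, n_model_params=n_model,
                         converged=True, spec=None, tree=None)

    def test_equal_likelihoods_give_p_one(self):
        null = self._fake_fit("M0", -100.0, 2)
        alt = self._fake_fit("branch2", -100.0, 3)
        r = likelihood_ratio_test(null, alt)
        assert r.stat == 0.0 and r.p_value == 1.0 and r.df == 1

    def test_chi2_quantile_identity(self):
        null = self._fake_fit("M0", -100.0, 2)
        alt = self._fake_fit("branch2", -100.0 + 3.841 / 2, 3)
        r = likelihood_ratio_test(null, alt)
        assert r.p_value == pytest.approx(0.05, abs=5e-4)

    def test_published_stat_both_df_conventions(self):
        # a 2*dlnL of 35.547 corresponds to p = 2.5e-9 at df 1 and
        # p = 1.9e-8 at df 2; an explicit df override selects between them
        null = self._fake_fit("M2a_rel", -5431.051, 5)
        alt = self._fake_fit("CmC", -5431.051 + 35.547 / 2, 6)
        r1 = likelihood_ratio_test(null, alt)
        assert r1.df == 1
        assert r1.p_value == pytest.approx(2.5e-9, rel=0.02)
        r2 = likelihood_ratio_test(null, alt, df=2)
        assert r2.p_value == pytest.approx(1.9e-8, rel=0.05)

    def test_worse_alternative_flags_optimizer_failure(self):
        null = self._fake_fit("M0", -100.0, 2)
        alt = self._fake_fit("branch2", -105.0, 3)
        with pytest.raises(ValueError, match="optimization failure"):
            likelihood_ratio_test(null, alt)

    def test_non_nested_pair_rejected(self):
        null = self._fake_fit("M1a", -100.0, 3)
        alt = self._fake_fit("CmC", -99.0, 6)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(null, alt)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_case(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_textbook_formula_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.uniform(0, 1, size=rng.integers(1, 12)).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFrequencies:
    def test_modes_sum_to_one(self):
        aln = CodonAlignment([
            SequenceRecord("a", "ATGAAATTTCTC", "dna"),
            SequenceRecord("b", "ATGAAGTTCCTC", "dna"),
        ])
        for mode in ("uniform", "F1x4", "F3x4", "F61"):
            f = CodonFrequencies.from_alignment(aln, mode)
            assert f.pi.sum() == pytest.approx(1.0)
            assert f.pi.min() > 0
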