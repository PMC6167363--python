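"""Substitution model, discrete gamma, pruning likelihoods, branch
optimization, and exhaustive topology enumeration."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import dimlight as dl
from dimlight import errors, phylo


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

class TestSubstitutionModel:
    def test_transition_matrix_stochastic(self, jtt):
        for t in (0.01, 0.1, 1.0, 10.0):
            P = jtt.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= 0).all()

    def test_identity_at_zero(self, jtt):
        assert np.allclose(jtt.transition_matrix(0.0), np.eye(20), atol=1e-12)

    def test_long_time_limit_is_stationary(self, jtt):
        P = jtt.transition_matrix(500.0)
        assert np.allclose(P, np.tile(jtt.frequencies, (20, 1)), atol=1e-10)

    def test_equal_rates_uniform_pi_is_jc_like(self):
        """Equal exchangeabilities + uniform frequencies: every
        off-diagonal transition probability is equal (Jukes-Cantor
        structure on 20 states)."""
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        m = dl.build_model(S, frequencies=np.full(20, 1 / 20))
        P = m.transition_matrix(0.5)
        off = P[~np.eye(20, dtype=bool)]
        assert np.allclose(off, off[0], atol=1e-12)

    def test_detailed_balance_and_unit_rate(self, jtt):
        flux = jtt.frequencies[:, None] * jtt.Q
        assert np.allclose(flux, flux.T, atol=1e-12)
        assert -(jtt.frequencies * np.diag(jtt.Q)).sum() == pytest.approx(1.0)

    def test_asymmetric_table_rejected(self):
        S = np.ones((20, 20))
        S[0, 1] = 2.0
        with pytest.raises(errors.AsymmetricTable):
            dl.build_model(S, frequencies=np.full(20, 1 / 20))

    def test_bad_frequencies_rejected(self):
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        with pytest.raises(errors.BadFrequencies):
            dl.build_model(S, frequencies=np.full(20, 1.0))

    def test_empirical_frequencies(self, jtt):
        aln = dl.io.alignment_from_sequences([("a", "AAAR"), ("b", "AARR")])
        m = dl.build_model("JTT", frequencies="empirical", alignment=aln)
        assert m.frequencies[0] == pytest.approx(5 / 8, rel=1e-3)


# ---------------------------------------------------------------------------
# Discrete gamma
# ---------------------------------------------------------------------------

class TestDiscreteGamma:
    def test_single_category(self):
        r = dl.discrete_gamma(0.5, 1)
        assert np.array_equal(r.rates, [1.0])

    @pytest.mark.parametrize("alpha", [0.1, 0.71, 0.93, 2.0, 50.0])
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_mean_one(self, alpha, k):
        r = dl.discrete_gamma(alpha, k)
        assert abs(r.rates.mean() - 1.0) < 1e-10

    @pytest.mark.parametrize("alpha", [0.25, 0.71, 0.93, 2.0])
    def test_rates_match_quadrature(self, alpha):
        """Category rates equal k * E[X; slice] by direct numerical
        integration of the gamma density (independent of the
        incomplete-gamma identity used in the implementation)."""
        k = 4
        r = dl.discrete_gamma(alpha, k)
        dist = gamma_dist(alpha, scale=1.0 / alpha)
        bounds = [0.0] + list(dist.ppf(np.arange(1, k) / k)) + [np.inf]
        for i in range(k):
            val, _ = quad(lambda x: x * dist.pdf(x), bounds[i], bounds[i + 1],
                          limit=200)
            assert abs(r.rates[i] - k * val) < 1e-8

    def test_bad_shape_rejected(self):
        with pytest.raises(errors.BadShape):
            dl.discrete_gamma(0.0, 4)
        with pytest.raises(errors.BadShape):
            dl.discrete_gamma(1.0, 0)


# ---------------------------------------------------------------------------
# Pruning likelihoods
# ---------------------------------------------------------------------------

def brute_force_site_lnl(tree, aln, model, rates):
    """Independent oracle: sum over all internal-node state assignments."""
    adj = tree.adjacency()
    n_tips = tree.n_tips
    internals = sorted(n for n in adj if n >= n_tips)
    pi = model.frequencies
    codes = {t: aln.sites[aln.taxa.index(t)] for t in aln.taxa}
    out = np.zeros(aln.n_sites)
    for site in range(aln.n_sites):
        tot = 0.0
        for rate in rates.rates:
            Ps = {}
            for u, v, w in tree.edges:
                P = model.transition_matrix(w * rate)
                Ps[(u, v)] = Ps[(v, u)] = P
            s = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                st = dict(zip(internals, assign))
                for i, name in enumerate(tree.tips):
                    st[i] = int(codes[name][site])
                p = pi[st[internals[0]]]
                seen = {internals[0]}
                stack = [internals[0]]
                while stack:
                    x = stack.pop()
                    for y, _ in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            p *= Ps[(x, y)][st[x], st[y]]
                            stack.append(y)
                s += p
            tot += s / rates.k
        out[site] = np.log(tot)
    return out


class TestSiteLogLikelihoods:
    def test_degenerate_star_tree_gives_log_pi(self, jtt):
        aln = dl.io.alignment_from_sequences([("A", "R"), ("B", "R"), ("C", "R")])
        tree = dl.read_newick("(A:0,B:0,C:0);")
        lnl = dl.site_log_likelihoods(aln, tree, jtt,
                                      dl.discrete_gamma(1.0, 1))
        assert lnl[0] == pytest.approx(np.log(jtt.frequencies[1]), abs=1e-12)

    def test_pruning_equals_brute_force(self, jtt, quartet_tree):
        rates = dl.discrete_gamma(0.71, 2)
        aln = dl.gen_alignment(quartet_tree, dl.EvolModel(jtt, rates), 5, seed=9)
        ours = dl.site_log_likelihoods(aln, quartet_tree, jtt, rates)
        oracle = brute_force_site_lnl(quartet_tree, aln, jtt, rates)
        assert np.abs(ours - oracle).max() < 1e-10

    def test_rerooting_invariance(self, jtt, gamma4):
        """The same unrooted tree written with different rootings gives
        identical per-site lnL (reversibility)."""
        forms = [
            "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07,E:0.25);",
            "(A:0.1,(B:0.2,((C:0.3,D:0.15):0.07,E:0.25):0.05):0.0);",
            "(((C:0.3,D:0.15):0.07,E:0.25):0.025,(A:0.1,B:0.2):0.025);",
        ]
        trees = [dl.read_newick(f) for f in forms]
        assert trees[0].splits() == trees[1].splits() == trees[2].splits()
        aln = dl.gen_alignment(trees[0], dl.EvolModel(jtt, gamma4), 40, seed=17)
        ref = dl.site_log_likelihoods(aln, trees[0], jtt, gamma4)
        for t in trees[1:]:
            assert np.abs(dl.site_log_likelihoods(aln, t, jtt, gamma4)
                          - ref).max() < 1e-10

    def test_ambiguous_residues_are_marginalized(self, jtt, quartet_tree):
        """Replacing a residue by X can only raise the site likelihood
        sum over states (it is a marginal over the 20 residues)."""
        rates = dl.discrete_gamma(1.0, 2)
        aln = dl.gen_alignment(quartet_tree, dl.EvolModel(jtt, rates), 3, seed=2)
        sites = aln.sites.copy()
        sites[0, 0] = dl.io.UNKNOWN
        masked = dl.Alignment(aln.taxa, sites)
        base = dl.site_log_likelihoods(aln, quartet_tree, jtt, rates)
        marg = dl.site_log_likelihoods(masked, quartet_tree, jtt, rates)
        assert marg[0] > base[0]
        assert np.allclose(marg[1:], base[1:], atol=1e-12)

    def test_gamma_large_alpha_matches_homogeneous(self, jtt, quartet_tree):
        rates_inf = dl.discrete_gamma(1e6, 4)
        rates_one = dl.discrete_gamma(1.0, 1)
        aln = dl.gen_alignment(quartet_tree, dl.EvolModel(jtt, rates_one),
                               50, seed=23)
        a = dl.site_log_likelihoods(aln, quartet_tree, jtt, rates_inf).sum()
        b = dl.site_log_likelihoods(aln, quartet_tree, jtt, rates_one).sum()
        assert abs(a - b) < 1e-6

    def test_taxon_mismatch_rejected(self, jtt, quartet_tree, gamma4):
        aln = dl.io.alignment_from_sequences(
            [("A", "AR"), ("B", "AR"), ("C", "AR"), ("Z", "AR")]
        )
        with pytest.raises(errors.TaxonMismatch):
            dl.site_log_likelihoods(aln, quartet_tree, jtt, gamma4)

    def test_reference_values_from_independent_engine(self, jtt):
        """Total lnL agrees with an independent phylogenetics engine
        (phangorn's pml, JTT, same discrete-gamma settings) on a frozen
        synthetic dataset, with and without rate heterogeneity."""
        tree = dl.read_newick(
            "((A:0.12,B:0.23):0.08,(C:0.31,D:0.05):0.11,E:0.4);"
        )
        rates = dl.discrete_gamma(0.93, 4)
        aln = dl.gen_alignment(tree, dl.EvolModel(jtt, rates), 60, seed=42)
        total = dl.site_log_likelihoods(aln, tree, jtt, rates).sum()
        assert total == pytest.approx(-467.8187137564, abs=1e-6)
        total1 = dl.site_log_likelihoods(aln, tree, jtt,
                                         dl.discrete_gamma(1.0, 1)).sum()
        assert total1 == pytest.approx(-471.8456980125, abs=1e-6)


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

class TestOptimizeBranchLengths:
    def test_never_decreases_likelihood(self, jtt, quartet_tree, gamma4):
        aln = dl.gen_alignment(quartet_tree, dl.EvolModel(jtt, gamma4),
                               80, seed=31)
        before = dl.site_log_likelihoods(aln, quartet_tree, jtt, gamma4).sum()
        _, after = dl.optimize_branch_lengths(aln, quartet_tree, jtt, gamma4)
        assert after >= before

    def test_idempotent(self, jtt, quartet_tree, gamma4):
        aln = dl.gen_alignment(quartet_tree, dl.EvolModel(jtt, gamma4),
                               80, seed=31)
        t1, l1 = dl.optimize_branch_lengths(aln, quartet_tree, jtt, gamma4)
        t2, l2 = dl.optimize_branch_lengths(aln, t1, jtt, gamma4)
        assert abs(l2 - l1) < 1e-6

    def test_consistency_large_sites(self, jtt):
        """10^4 sites on a quartet: ML branch lengths within 10% of the
        generating values."""
        tree = dl.read_newick("((A:0.2,B:0.3):0.15,C:0.25,D:0.4);")
        rates = dl.discrete_gamma(1.0, 1)
        aln = dl.gen_alignment(tree, dl.EvolModel(jtt, rates), 10_000, seed=77)
        opt, _ = dl.optimize_branch_lengths(aln, tree, jtt, rates)
        true = {frozenset((u, v)): w for u, v, w in tree.edges}
        for u, v, w in opt.edges:
            assert abs(w - true[frozenset((u, v))]) / true[frozenset((u, v))] < 0.10


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

class TestEnumerateTopologies:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105),
                                         (7, 945), (8, 10395)])
    def test_double_factorial_counts(self, n, count):
        tips = [f"t{i}" for i in range(n)]
        topos = dl.enumerate_topologies(tips)
        assert len(topos) == count

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_all_shapes_distinct(self, n):
        tips = [f"t{i}" for i in range(n)]
        topos = dl.enumerate_topologies(tips)
        assert len({t.splits() for t in topos}) == len(topos)

    def test_constraint_reduces_to_effective_units(self):
        tips = ["RH1", "RH2", "SWS2", "SWS1", "LWS", "P", "VA", "Opn3"]
        topos = dl.enumerate_topologies(
            tips, constraint="(((RH1,RH2),SWS2),SWS1);"
        )
        assert len(topos) == 15
        fixed = frozenset({"RH1", "RH2"})
        for t in topos:
            assert t.n_tips == 8
            assert fixed in t.splits()

    def test_too_many_tips(self):
        with pytest.raises(errors.TooManyTips):
            dl.enumerate_topologies([f"t{i}" for i in range(9)])

    def test_deterministic_order(self):
        a = dl.enumerate_topologies(["w", "x", "y", "z"])
        b = dl.enumerate_topologies(["w", "x", "y", "z"])
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]


# ---------------------------------------------------------------------------
# Exhaustive ML and bootstrap
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def five_taxon_run():
    jtt = dl.build_model("JTT")
    tree = dl.read_newick(
        "(((A:0.15,B:0.15):0.1,C:0.2):0.1,D:0.25,E:0.3);"
    )
    rates = dl.discrete_gamma(1.0, 4)
    aln = dl.gen_alignment(tree, dl.EvolModel(jtt, rates), 300, seed=11)
    result = dl.exhaustive_ml(aln, jtt, alpha=1.0, k=4)
    return tree, aln, jtt, result


class TestExhaustiveML:
    def test_recovers_generating_topology(self, five_taxon_run):
        tree, _, _, result = five_taxon_run
        assert result.ml_topology.same_shape(tree)

    def test_matrix_bookkeeping(self, five_taxon_run):
        _, _, _, result = five_taxon_run
        assert result.matrix.L.shape == (300, 15)
        assert (result.matrix.L <= 0).all()
        assert np.allclose(result.matrix.totals(), result.matrix.L.sum(axis=0),
                           atol=1e-9)

    def test_site_permutation_leaves_totals_unchanged(self, five_taxon_run,
                                                      rng):
        tree, aln, jtt, result = five_taxon_run
        perm = rng.permutation(aln.n_sites)
        shuffled = dl.Alignment(aln.taxa, aln.sites[:, perm])
        res2 = dl.exhaustive_ml(shuffled, jtt, alpha=1.0, k=4)
        assert np.allclose(np.sort(res2.matrix.totals()),
                           np.sort(result.matrix.totals()), atol=1e-4)

    def test_bootstrap_single_replicate_binary(self, five_taxon_run):
        _, _, _, result = five_taxon_run
        bp = dl.bootstrap_support(result, B=1, seed=5)
        assert set(bp.values()) <= {0.0, 1.0}

    def test_strong_split_high_support(self, jtt):
        """A long internal branch is recovered with BP >= 0.95 at B=200."""
        tree = dl.read_newick("((A:0.1,B:0.1):0.5,C:0.1,D:0.1);")
        rates = dl.discrete_gamma(1.0, 1)
        aln = dl.gen_alignment(tree, dl.EvolModel(jtt, rates), 300, seed=13)
        result = dl.exhaustive_ml(aln, jtt, alpha=1.0, k=1)
        bp = dl.bootstrap_support(result, B=200, seed=3)
        assert bp.get(frozenset({"C", "D"}), 0.0) >= 0.95

    def test_quartet_support_partitions(self, jtt):
        """The three resolutions of a quartet get supports summing to 1."""
        tree = dl.read_newick("((A:0.2,B:0.2):0.05,C:0.2,D:0.2);")
        rates = dl.discrete_gamma(1.0, 1)
        aln = dl.gen_alignment(tree, dl.EvolModel(jtt, rates), 100, seed=19)
        result = dl.exhaustive_ml(aln, jtt, alpha=1.0, k=1)
        bp = dl.bootstrap_support(result, B=100, seed=7)
        assert sum(bp.values()) == pytest.approx(1.0)
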