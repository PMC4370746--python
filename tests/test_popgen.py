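"""Genotype statistics: frequencies, HWE, F_ST, assignment, exclusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from nataltrack.popgen import (
    GenotypeTable,
    PopulationLookupError,
    allele_freqs,
    classify_juveniles,
    exclusion_test,
    filter_loci,
    frequency_likelihood,
    fst_weir_cockerham,
    hwe_exact_test,
    read_genepop,
    self_assign_loo,
    write_genepop,
)
from nataltrack.synthetic import gen_genotypes
from conftest import LOCI_12, make_truth


def table_from_calls(calls_by_pop, loci=None):
    """calls_by_pop: {pop: array-like (n, L, 2)}."""
    pops, blocks = zip(*calls_by_pop.items())
    calls = np.concatenate([np.asarray(b) for b in blocks])
    labels = sum([[p] * len(np.asarray(b)) for p, b in
                  calls_by_pop.items()], [])
    n = calls.shape[0]
    loci = loci or [f"L{j}" for j in range(calls.shape[1])]
    individuals = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                                "population": labels, "year": 2006,
                                "tl_mm": 7.0})
    return GenotypeTable(individuals=individuals, loci=loci, calls=calls)


class TestAlleleFreqs:
    def test_fixed_population(self):
        t = table_from_calls({"A": [[[1, 1]], [[1, 1]]]})
        f = allele_freqs(t, "A")
        assert f.frequencies[0] == {1: 1.0}

    def test_simple_counts(self):
        t = table_from_calls({"A": [[[1, 1]], [[1, 2]]]})
        f = allele_freqs(t, "A")
        assert f.frequencies[0] == {1: 0.75, 2: 0.25}

    def test_matches_brute_force_tally(self, weak_table):
        f = allele_freqs(weak_table, "NS")
        rows = weak_table.population_index("NS")
        for j in range(len(weak_table.loci)):
            tally = {}
            for i in rows:
                for a in weak_table.calls[i, j]:
                    if a != 0:
                        tally[a] = tally.get(a, 0) + 1
            total = sum(tally.values())
            for a, c in tally.items():
                assert f.frequencies[j][a] == pytest.approx(c / total)
            assert sum(f.frequencies[j].values()) == pytest.approx(
                1.0, abs=1e-12)

    def test_missing_population_raises(self, weak_table):
        with pytest.raises(PopulationLookupError):
            allele_freqs(weak_table, "nope")


def hwe_exact_biallelic(calls):
    """Full-enumeration exact HWE p-value for a biallelic locus.

    Enumerates every heterozygote count compatible with the observed
    allele counts; the p-value is the total probability of tables no
    more probable than the observed one (Levene's conditional
    distribution).
    """
    calls = np.asarray(calls)
    n = calls.shape[0]
    nA = int(np.count_nonzero(calls == 1))
    h_obs = int(np.count_nonzero(calls[:, 0] != calls[:, 1]))

    def log_prob(h):
        nAA = (nA - h) // 2
        naa = n - nAA - h
        if nAA < 0 or naa < 0:
            return -np.inf
        return (gammaln(n + 1) - gammaln(nAA + 1) - gammaln(h + 1)
                - gammaln(naa + 1) + h * np.log(2)
                + gammaln(nA + 1) + gammaln(2 * n - nA + 1)
                - gammaln(2 * n + 1))

    hs = [h for h in range(nA % 2, min(nA, 2 * n - nA) + 1, 2)]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(h_obs)]
    return probs[probs <= p_obs + 1e-12].sum()


class TestHwe:
    def test_monomorphic_is_one(self):
        r = hwe_exact_test(np.full((10, 2), 3))
        assert r.p_value == 1.0

    def test_all_missing_flagged_undefined(self):
        r = hwe_exact_test(np.zeros((5, 2), dtype=int))
        assert not r.defined

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_biallelic_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([1, 2], size=(40, 2), p=[0.6, 0.4])
        exact = hwe_exact_biallelic(calls)
        mc = hwe_exact_test(calls, n_permutations=20_000, seed=seed)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert mc.p_value == pytest.approx(exact, abs=max(4 * se, 5e-3))

    def test_determinism(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([1, 2, 3], size=(30, 2))
        p1 = hwe_exact_test(calls, n_permutations=2000, seed=7).p_value
        p2 = hwe_exact_test(calls, n_permutations=2000, seed=7).p_value
        assert p1 == p2


class TestFilterLoci:
    def test_published_violation_pattern(self, hwe_flags):
        retained = filter_loci(hwe_flags)
        assert set(LOCI_12) - set(retained) == {
            "YP78", "YP96", "YP60", "YP65", "YP49"}
        assert len(retained) == 7

    def test_no_violations_keeps_all(self, hwe_flags):
        clean = hwe_flags.assign(significant=False)
        assert filter_loci(clean) == LOCI_12

    def test_single_pop_single_year_violation_retained(self, hwe_flags):
        flags = hwe_flags.assign(significant=False)
        flags.loc[(flags["locus"] == "YP85")
                  & (flags["population"] == "NS")
                  & (flags["year"] == 2006), "significant"] = True
        assert "YP85" in filter_loci(flags)


def wc_theta_oracle(table, pop_a, pop_b):
    """Independent spreadsheet-style Weir–Cockerham computation.

    Plain per-allele loops writing out n̄, n_c, p̄, s², h̄ and the three
    variance components exactly as published.
    """
    idx = {p: table.population_index(p) for p in (pop_a, pop_b)}
    r = 2
    A = B = C = 0.0
    for j in range(len(table.loci)):
        sub = {}
        for p in (pop_a, pop_b):
            c = table.calls[idx[p], j]
            sub[p] = c[(c != 0).all(axis=1)]
        ns = [len(sub[pop_a]), len(sub[pop_b])]
        alleles = sorted(set(sub[pop_a].ravel()) | set(sub[pop_b].ravel()))
        if len(alleles) < 2 or min(ns) < 1:
            continue
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(x * x for x in ns) / sum(ns)) / (r - 1)
        for al in alleles:
            ps, hs = [], []
            for p in (pop_a, pop_b):
                g = sub[p]
                ps.append(np.count_nonzero(g == al) / (2 * len(g)))
                hs.append(np.count_nonzero(
                    (g == al).sum(axis=1) == 1) / len(g))
            pbar = sum(n * p_ for n, p_ in zip(ns, ps)) / sum(ns)
            s2 = sum(n * (p_ - pbar) ** 2
                     for n, p_ in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
            a = nbar / nc * (s2 - 1 / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            A += a
            B += b
            C += hbar / 2
    return A / (A + B + C)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        t = table_from_calls({
            "A": np.full((4, 2, 2), 1), "B": np.full((4, 2, 2), 2)})
        theta, per_locus = fst_weir_cockerham(t, "A", "B")
        assert theta == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in per_locus.values())

    def test_random_split_is_near_zero(self):
        truth = make_truth(100, regions=("P",))
        tab = gen_genotypes(truth, n_loci=7, F=0.0, seed=3)
        half = ["X"] * 100
        tab.individuals["population"] = half[:50] + ["Y"] * 50
        theta, _ = fst_weir_cockerham(tab, "X", "Y")
        assert abs(theta) < 0.02

    def test_toy_table_matches_hand_computation(self):
        t = table_from_calls({
            "A": [[[1, 1], [1, 2]], [[1, 2], [2, 2]], [[1, 1], [1, 1]]],
            "B": [[[2, 2], [1, 2]], [[1, 2], [2, 2]], [[2, 2], [1, 2]]]})
        theta, _ = fst_weir_cockerham(t, "A", "B")
        assert theta == pytest.approx(wc_theta_oracle(t, "A", "B"),
                                      abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_tables_match_oracle(self, seed):
        tab = gen_genotypes(make_truth(20), n_loci=5, F=0.1, seed=seed)
        theta, _ = fst_weir_cockerham(tab, "NS", "SS")
        assert theta == pytest.approx(wc_theta_oracle(tab, "NS", "SS"),
                                      abs=1e-10)

    def test_invariant_under_relabelling_and_swap(self, weak_table):
        theta, _ = fst_weir_cockerham(weak_table, "NS", "SS")
        swapped, _ = fst_weir_cockerham(weak_table, "SS", "NS")
        assert theta == pytest.approx(swapped, abs=1e-12)
        relab = GenotypeTable(
            individuals=weak_table.individuals.copy(),
            loci=list(weak_table.loci),
            calls=np.where(weak_table.calls > 0,
                           17 - weak_table.calls, 0))
        theta2, _ = fst_weir_cockerham(relab, "NS", "SS")
        assert theta == pytest.approx(theta2, abs=1e-12)


class TestFrequencyLikelihood:
    def _freqs(self, per_locus):
        t = table_from_calls({"A": [[[1, 1]] * len(per_locus)]})
        f = allele_freqs(t, "A")
        f.frequencies = [dict(d) for d in per_locus]
        f.n_copies = np.full(len(per_locus), 100)
        return f

    def test_homozygote_p_squared(self):
        f = self._freqs([{1: 0.5, 2: 0.5}])
        ll = frequency_likelihood(np.array([[1, 1]]), f)
        assert np.exp(ll) == pytest.approx(0.25)

    def test_heterozygote_2pq(self):
        f = self._freqs([{1: 0.3, 2: 0.2, 3: 0.5}])
        ll = frequency_likelihood(np.array([[1, 2]]), f)
        assert np.exp(ll) == pytest.approx(0.12)

    def test_unseen_allele_floored(self):
        f = self._freqs([{1: 1.0}])
        ll = frequency_likelihood(np.array([[9, 9]]), f)
        assert np.exp(ll) == pytest.approx(0.01 ** 2)

    def test_multilocus_product(self):
        per = [{1: 0.5, 2: 0.5}, {1: 0.3, 2: 0.7}, {1: 0.9, 2: 0.1}]
        f = self._freqs(per)
        g = np.array([[1, 1], [1, 2], [2, 2]])
        expected = 0.25 * (2 * 0.3 * 0.7) * 0.01
        ll = frequency_likelihood(g, f)
        assert np.exp(ll) == pytest.approx(expected, rel=1e-12)

    def test_missing_loci_skipped_all_missing_raises(self):
        f = self._freqs([{1: 1.0}, {1: 0.5, 2: 0.5}])
        ll = frequency_likelihood(np.array([[0, 0], [1, 2]]), f)
        assert np.exp(ll) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            frequency_likelihood(np.zeros((2, 2), dtype=int), f)


def self_assign_loo_bruteforce(table, pop_a, pop_b):
    """Naive LOO: rebuild the whole table without each individual."""
    calls = []
    for p_self, p_other in ((pop_a, pop_b), (pop_b, pop_a)):
        for i in table.population_index(p_self):
            keep = np.ones(table.n, dtype=bool)
            keep[i] = False
            loo_table = table.subset(np.flatnonzero(keep))
            f_self = allele_freqs(loo_table, p_self)
            f_other = allele_freqs(loo_table, p_other)
            ll_s = frequency_likelihood(table.calls[i], f_self)
            ll_o = frequency_likelihood(table.calls[i], f_other)
            call = p_self if ll_s > ll_o else p_other
            if ll_s == ll_o:
                call = pop_a
            calls.append((table.individuals["id"].iloc[i], call))
    return calls


class TestSelfAssignLoo:
    def test_fixed_pops_fully_accurate(self):
        t = table_from_calls({
            "A": np.full((5, 3, 2), 1), "B": np.full((5, 3, 2), 2)})
        _, acc = self_assign_loo(t, "A", "B")
        assert acc["overall"] == 100.0

    def test_identical_pops_near_chance(self):
        truth = make_truth(120, regions=("P",))
        tab = gen_genotypes(truth, n_loci=7, F=0.0, seed=5)
        tab.individuals["population"] = ["X"] * 60 + ["Y"] * 60
        _, acc = self_assign_loo(tab, "X", "Y")
        # binomial chance band: 50 +- 4 sigma over 120 calls
        assert abs(acc["overall"] - 50.0) < 400 / np.sqrt(120)

    def test_matches_bruteforce_recomputation(self, weak_table):
        calls_df, _ = self_assign_loo(weak_table, "NS", "SS")
        brute = dict(self_assign_loo_bruteforce(weak_table, "NS", "SS"))
        for _, row in calls_df.iterrows():
            assert row["call"] == brute[row["id"]]


class TestExclusion:
    def test_common_homozygote_has_high_p(self, divergent_table):
        f = allele_freqs(divergent_table, "NS")
        g = np.array([[max(d, key=d.get)] * 2 for d in f.frequencies])
        p = exclusion_test(g, f, n_sim=2000, seed=0)
        assert p > 0.5

    def test_foreign_alleles_excluded(self, divergent_table):
        f = allele_freqs(divergent_table, "NS")
        g = np.full((len(f.loci), 2), 99)
        p = exclusion_test(g, f, n_sim=2000, seed=0)
        assert p <= 0.001

    def test_reference_draws_are_uniformish(self):
        """p-values of genotypes truly drawn from the reference."""
        from scipy import stats

        rng = np.random.default_rng(12)
        t = gen_genotypes(make_truth(200, regions=("R",)), n_loci=7,
                          F=0.0, seed=12)
        f = allele_freqs(t, "R")
        ps = []
        for k in range(100):
            g = np.array([
                [rng.choice(list(d), p=list(d.values())) for _ in range(2)]
                for d in f.frequencies])
            ps.append(exclusion_test(g, f, n_sim=2000,
                                     seed=int(rng.integers(2**31))))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClassifyJuveniles:
    def test_pure_profile_assigned(self):
        ref = table_from_calls({
            "NS": np.full((6, 4, 2), 1), "SS": np.full((6, 4, 2), 2)})
        juv = table_from_calls({"unknown": np.full((3, 4, 2), 1)})
        calls, summary = classify_juveniles(juv, ref, "NS", "SS",
                                            n_sim=500, seed=0)
        assert all(c.assigned_population == "NS" for c in calls)
        assert summary["pct_NS"] == 100.0

    def test_balanced_score_fails(self):
        ref = table_from_calls({
            "NS": [[[1, 1], [2, 2]]] * 6, "SS": [[[2, 2], [1, 1]]] * 6})
        juv = table_from_calls({"unknown": [[[1, 1], [1, 1]]]})
        calls, _ = classify_juveniles(juv, ref, "NS", "SS",
                                      exclude_below=0.0,
                                      n_sim=500, seed=0)
        assert calls[0].status == "failed"
        assert calls[0].score_north == pytest.approx(0.5)

    def test_mixture_recovery_high_divergence(self):
        truth = pd.concat([
            make_truth(60),
            make_truth(25, regions=("NS",), role="juvenile"),
            make_truth(15, regions=("SS",), role="juvenile")],
            ignore_index=True)
        truth["id"] = [f"x{k}" for k in range(len(truth))]
        tab = gen_genotypes(truth, n_loci=7, F=0.3, seed=21)
        known = tab.subset(np.flatnonzero(
            tab.individuals["population"] != "unknown"))
        juv = tab.subset(np.flatnonzero(
            tab.individuals["population"] == "unknown"))
        _, summary = classify_juveniles(juv, known, "NS", "SS",
                                        n_sim=1000, seed=2)
        est = summary["pct_NS"] / (summary["pct_NS"] + summary["pct_SS"])
        # truth 25/40; binomial 95% half-width at n=40 is ~0.15
        assert est == pytest.approx(25 / 40, abs=0.16)


class TestGenepopIO:
    def test_roundtrip(self, tmp_path, weak_table):
        path = tmp_path / "larvae.gen"
        write_genepop(weak_table, path)
        back = read_genepop(path, pop_names=["NS", "SS"])
        assert back.loci == weak_table.loci
        np.testing.assert_array_equal(back.calls, weak_table.calls)
        assert list(back.individuals["population"]) == \
            list(weak_table.individuals["population"])

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("title\nL1\nPop\nind1  001001\n")
        with pytest.raises(ValueError):
            read_genepop(path)
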