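"""Diversity summaries, exact HWE testing, private alleles, F-statistics."""

import numpy as np
import pytest

import strpanel as sp
from strpanel import diversity
from strpanel.diversity import hwe_exact_test
from strpanel.genotypes import (
    MISSING,
    GenotypeTable,
    LocusDefinition,
    MultilocusGenotype,
    canonical,
)


def table_from_counts(genotype_counts, locus="LA"):
    inds = []
    i = 0
    for g, n in genotype_counts.items():
        for _ in range(n):
            inds.append(
                MultilocusGenotype(sample_id=f"s{i}", calls={locus: canonical(g)})
            )
            i += 1
    return GenotypeTable(loci=[LocusDefinition(name=locus)], individuals=inds)


class TestLocusSummary:
    def test_known_values_p07(self):
        # p = (0.7, 0.3): Ne = 1/0.58, I = -sum p ln p
        t = table_from_counts({(1, 1): 49, (1, 2): 42, (2, 2): 9})
        s = diversity.locus_summary(t, "LA")
        assert s.A == 2
        assert s.Ne == pytest.approx(1.7241, abs=1e-4)
        assert s.I == pytest.approx(0.6109, abs=1e-4)
        assert s.He == pytest.approx(0.42)
        assert s.Ho == pytest.approx(0.42)
        assert s.uHe == pytest.approx(0.42 * 200 / 199)

    def test_monomorphic(self):
        t = table_from_counts({(5, 5): 10})
        s = diversity.locus_summary(t, "LA")
        assert (s.A, s.Ne, s.He, s.I, s.Ho) == (1, 1.0, 0.0, 0.0, 0.0)
        assert s.hwe_p == 1.0

    def test_he_equals_one_minus_inverse_ne(self, abb_table):
        for lo in [l.name for l in abb_table.autosomal_loci]:
            s = diversity.locus_summary(t := abb_table, lo)
            assert s.He == pytest.approx(1 - 1 / s.Ne, abs=1e-12)

    def test_shannon_maximal_for_uniform(self):
        t = table_from_counts({(1, 2): 10, (3, 4): 10})
        s = diversity.locus_summary(t, "LA")
        assert s.I == pytest.approx(np.log(4), abs=1e-12)


class TestHWEExact:
    def test_perfect_proportions_not_rejected(self):
        assert hwe_exact_test({(1, 1): 25, (1, 2): 50, (2, 2): 25}) > 0.9

    def test_all_heterozygotes_rejected(self):
        # 20 individuals, all A/B: extreme heterozygote excess
        assert hwe_exact_test({(1, 2): 20}) < 0.01

    def test_two_sided_tail_matches_direct_enumeration(self):
        # independent oracle: enumerate heterozygote counts for the
        # diallelic conditional law directly from the urn formula
        from math import comb

        obs = {(1, 1): 6, (1, 2): 3, (2, 2): 6}
        n, n1 = 15, 15  # 15 individuals, 15 copies of allele 1
        def prob(h):  # h hets, (n1-h)/2 hom11
            if (n1 - h) % 2:
                return 0.0
            f11 = (n1 - h) // 2
            f22 = n - h - f11
            if f11 < 0 or f22 < 0:
                return 0.0
            from math import factorial as f

            return (
                f(n) / (f(f11) * f(h) * f(f22))
                * 2**h
                * f(n1) * f(2 * n - n1) / f(2 * n)
            )

        probs = {h: prob(h) for h in range(n1 + 1)}
        p_obs = probs[3]
        expected = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert hwe_exact_test(obs) == pytest.approx(expected, abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self, monkeypatch):
        counts = {(1, 1): 10, (1, 2): 30, (2, 2): 5, (1, 3): 10, (3, 3): 5}
        exact = hwe_exact_test(counts)
        monkeypatch.setattr(diversity, "_ENUM_LIMIT", 1)
        mc = hwe_exact_test(counts, n_mc=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_chi2_fallback_above_four_alleles(self):
        counts = {}
        for a in range(1, 6):
            counts[(a, a)] = 10
            for b in range(a + 1, 6):
                counts[(a, b)] = 8
        p = hwe_exact_test(counts)
        assert 0.0 <= p <= 1.0

    def test_type_one_error_calibration_smoke(self):
        # short version of the full 1000-rep calibration in acceptance
        rng = np.random.default_rng(17)
        p = 0.643
        probs = [p * p, 2 * p * (1 - p), (1 - p) ** 2]
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            c = rng.multinomial(113, probs)
            gc = {
                g: int(k)
                for g, k in zip([(1, 1), (1, 2), (2, 2)], c)
                if k
            }
            rej += hwe_exact_test(gc) < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.04)


class TestPrivateAlleles:
    def _two_group_table(self, calls_a, calls_b):
        inds, groups = [], {}
        for i, c in enumerate(calls_a):
            sid = f"a{i}"
            inds.append(MultilocusGenotype(sample_id=sid, calls={"LA": c}))
            groups[sid] = "A"
        for i, c in enumerate(calls_b):
            sid = f"b{i}"
            inds.append(MultilocusGenotype(sample_id=sid, calls={"LA": c}))
            groups[sid] = "B"
        return GenotypeTable(
            loci=[LocusDefinition(name="LA")], individuals=inds, groups=groups
        )

    def test_identical_allele_sets_yield_zero(self):
        t = self._two_group_table([(1, 2)] * 3, [(1, 2)] * 3)
        rep = sp.private_alleles(t)
        assert rep.per_locus == {"A": {"LA": 0}, "B": {"LA": 0}}

    def test_exclusive_allele_counted_once(self):
        t = self._two_group_table([(1, 126), (1, 1)], [(1, 2), (2, 2)])
        rep = sp.private_alleles(t)
        assert rep.per_locus["A"]["LA"] == 1  # 126 only in A
        assert rep.per_locus["B"]["LA"] == 1  # 2 only in B

    def test_single_group_rejected(self):
        t = self._two_group_table([(1, 2)], [])
        t.groups = {"a0": "A"}
        with pytest.raises(ValueError):
            sp.private_alleles(t)

    @pytest.mark.parametrize("seed", range(10))
    def test_set_difference_oracle(self, seed):
        from conftest import make_random_table

        t = make_random_table(seed, with_sex_marker=False)
        if len(set(t.groups.values())) < 2:
            return
        rep = sp.private_alleles(t)
        groups = sorted(set(t.groups.values()))
        for g in groups:
            for lo in t.locus_names:
                mine, others = set(), set()
                for ind in t.individuals:
                    c = ind.call(lo)
                    if c is MISSING:
                        continue
                    tgt = mine if t.groups.get(ind.sample_id) == g else others
                    tgt.update(c)
                assert rep.per_locus[g][lo] == len(mine - others)


class TestWCFstats:
    def _hwe_two_groups(self, n, seed, freqs=(0.5, 0.3, 0.2)):
        from strpanel.simulate import SimLocus, SimulationConfig

        cfg = SimulationConfig(
            loci=tuple(
                SimLocus(
                    name=f"L{j}", alleles=(100, 102, 104),
                    frequencies=freqs,
                )
                for j in range(5)
            ),
            n_individuals=2 * n, sib_family_fraction=0.0, seed=seed,
        )
        t = sp.sample_population(cfg)
        groups = {
            g.sample_id: ("A" if i < n else "B")
            for i, g in enumerate(t.individuals)
        }
        return t, groups

    def test_null_fst_near_zero(self):
        t, groups = self._hwe_two_groups(2500, seed=8)
        rows, jack = sp.wc_fstats(t, groups)
        assert abs(jack.fst) < 0.005
        assert jack.fst_se >= 0.0

    def test_duplicated_group_gives_nonpositive_fst(self):
        t, _ = self._hwe_two_groups(50, seed=9)
        # same individuals in both groups: no between-group variance at all,
        # the unbiased estimator may go slightly negative, never positive
        inds = list(t.individuals)
        dup = [
            MultilocusGenotype(sample_id=g.sample_id + "_dup", calls=dict(g.calls))
            for g in inds
        ]
        t2 = GenotypeTable(loci=t.loci, individuals=inds + dup, groups={})
        groups = {g.sample_id: "A" for g in inds}
        groups.update({g.sample_id: "B" for g in dup})
        _, jack = sp.wc_fstats(t2, groups)
        assert jack.fst <= 1e-12

    def test_multilocus_within_per_locus_range(self, abb_table):
        groups = {
            g.sample_id: ("p1" if i % 2 else "p2")
            for i, g in enumerate(abb_table.individuals)
        }
        rows, jack = sp.wc_fstats(abb_table, groups)
        fsts = [r.fst for r in rows]
        assert min(fsts) - 1e-12 <= jack.fst <= max(fsts) + 1e-12

    def test_locus_typed_in_one_group_excluded_with_warning(self):
        inds = [
            MultilocusGenotype(sample_id="a1", calls={"LA": (1, 2), "LB": (1, 2)}),
            MultilocusGenotype(sample_id="a2", calls={"LA": (1, 1), "LB": (2, 2)}),
            MultilocusGenotype(sample_id="b1", calls={"LA": (1, 2), "LB": MISSING}),
            MultilocusGenotype(sample_id="b2", calls={"LA": (2, 2), "LB": MISSING}),
        ]
        t = GenotypeTable(
            loci=[LocusDefinition(name="LA"), LocusDefinition(name="LB")],
            individuals=inds,
        )
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        with pytest.warns(UserWarning, match="LB"):
            rows, _ = sp.wc_fstats(t, groups)
        assert [r.locus for r in rows] == ["LA"]

    def test_island_model_recovery_smoke(self):
        # Balding-Nichols demes at F = 0.10; full 50-rep study in acceptance
        def one(seed):
            rng = np.random.default_rng(seed)
            a = 0.5 * 0.9 / 0.1
            inds, groups = [], {}
            L, n = 20, 150
            for d in range(2):
                ps = rng.beta(a, a, size=L)
                for i in range(n):
                    sid = f"{d}_{i}"
                    calls = {
                        f"L{j}": canonical(
                            1 + (rng.random(2) > ps[j]).astype(int)
                        )
                        for j in range(L)
                    }
                    inds.append(MultilocusGenotype(sample_id=sid, calls=calls))
                    groups[sid] = str(d)
            t = GenotypeTable(
                loci=[LocusDefinition(name=f"L{j}") for j in range(L)],
                individuals=inds, groups=groups,
            )
            return sp.wc_fstats(t)[1].fst

        ests = [one(s) for s in range(10)]
        assert np.mean(ests) == pytest.approx(0.10, abs=0.04)
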