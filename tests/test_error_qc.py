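"""Replicate-based QC: error rates, consensus, reliability, the QC loop."""

import itertools

import numpy as np
import pytest
from dataclasses import replace

import strpanel as sp
from strpanel.error_qc import (
    ConsensusRule,
    ConsensusStatus,
    QCConfig,
    consensus_genotype,
    estimate_error_rates,
    genotype_reliability,
    locus_reliability,
    null_allele_check,
    qc_loop,
)
from strpanel.genotypes import (
    MISSING,
    GenotypeTable,
    LocusDefinition,
    MultilocusGenotype,
    ReplicateSet,
    canonical,
)
from strpanel.simulate import SimLocus, SimulationConfig


def rset(sample_id, calls, locus="LA"):
    return ReplicateSet(
        sample_id=sample_id, replicates=[{locus: c} for c in calls]
    )


def cons(sample_id, call, locus="LA"):
    return MultilocusGenotype(sample_id=sample_id, calls={locus: call})


class TestEstimateErrorRates:
    def test_direct_counts(self):
        # truth A/B observed as (AB, AA, AB, BB): two false homozygotes
        rs = rset("s1", [(1, 2), (1, 1), (1, 2), (2, 2)])
        r = estimate_error_rates([rs], {"s1": cons("s1", (1, 2))})[0]
        assert (r.ado, r.fa) == (0.5, 0.0)
        assert (r.n_het_amplifications, r.n_amplifications) == (4, 4)

    def test_clean_replicates(self):
        rs = rset("s1", [(1, 2)] * 4)
        r = estimate_error_rates([rs], {"s1": cons("s1", (1, 2))})[0]
        assert (r.ado, r.fa) == (0.0, 0.0)

    def test_false_allele_counted_against_consensus(self):
        rs = rset("s1", [(1, 2), (1, 3), (1, 2), (1, 2)])
        r = estimate_error_rates([rs], {"s1": cons("s1", (1, 2))})[0]
        assert r.fa == 0.25
        assert r.ado == 0.0  # (1,3) is not a false homozygote

    def test_ado_undefined_without_het_consensus(self):
        rs = rset("s1", [(1, 1)] * 4)
        r = estimate_error_rates([rs], {"s1": cons("s1", (1, 1))})[0]
        assert r.ado is None
        assert r.fa == 0.0

    def test_scale_invariance(self):
        rs = rset("s1", [(1, 2), (1, 1), (1, 2), (2, 2)])
        consensus = {"s1": cons("s1", (1, 2)), "s2": cons("s2", (1, 2))}
        rs2 = ReplicateSet(sample_id="s2", replicates=rs.replicates)
        one = estimate_error_rates([rs], consensus)[0]
        both = estimate_error_rates([rs, rs2], consensus)[0]
        assert (one.ado, one.fa) == (both.ado, both.fa)

    def test_recovery_against_generator(self):
        # CXX20-like conditions: ado=0.085, fa=0.023, 5,000 positive
        # replicates; the counting estimator lands within 3 MC SEs
        cfg = sp.abb_like_config(seed=11)
        cfg = replace(
            cfg, n_individuals=1250, sib_family_fraction=0.0, missing_rate=0.0
        )
        t = sp.sample_population(cfg)
        rsets = [
            sp.amplify_replicates(g, cfg, loci=["CXX20"]) for g in t.individuals
        ]
        truth = {g.sample_id: g for g in t.individuals}
        r = estimate_error_rates(rsets, truth, loci=["CXX20"])[0]
        se_ado = np.sqrt(0.085 * 0.915 / r.n_het_amplifications)
        se_fa = np.sqrt(0.023 * 0.977 / r.n_amplifications)
        assert r.n_amplifications == 5000
        assert r.ado == pytest.approx(0.085, abs=3 * se_ado)
        assert r.fa == pytest.approx(0.023, abs=3 * se_fa)


class TestConsensus:
    def test_supported_heterozygote(self):
        res = consensus_genotype(rset("s", [(1, 2)] * 4))
        assert res.consensus.call("LA") == (1, 2)
        assert res.status is ConsensusStatus.ACCEPTED
        assert res.support["LA"] == {1: 4, 2: 4}

    def test_single_observation_of_second_allele_unresolved(self):
        res = consensus_genotype(rset("s", [(1, 1), (1, 1), (1, 2), (1, 1)]))
        assert res.consensus.call("LA") is MISSING
        assert res.unresolved_loci == ["LA"]
        assert res.status is ConsensusStatus.NEEDS_REPLICATES

    def test_homozygote_needs_three_concordant(self):
        ok = consensus_genotype(rset("s", [(1, 1)] * 3))
        assert ok.consensus.call("LA") == (1, 1)
        short = consensus_genotype(rset("s", [(1, 1)] * 2))
        assert short.consensus.call("LA") is MISSING

    def test_all_missing_locus(self):
        res = consensus_genotype(rset("s", [MISSING, MISSING]))
        assert res.consensus.call("LA") is MISSING
        assert res.unresolved_loci == []  # nothing amplified, nothing to resolve

    def test_mixture_flagged(self):
        res = consensus_genotype(rset("s", [(1, 2, 3)] * 4))
        assert res.status is ConsensusStatus.MIXED
        assert res.mixed_loci == ["LA"]

    def test_error_free_simulation_recovers_truth(self, abb_cfg):
        cfg = replace(
            abb_cfg,
            loci=tuple(replace(l, ado=0.0, fa=0.0) for l in abb_cfg.loci),
            missing_rate=0.0,
        )
        t = sp.sample_population(cfg)
        for g in t.individuals[:25]:
            rs = sp.amplify_replicates(g, cfg)
            res = consensus_genotype(rs, loci=cfg.locus_names)
            for l in cfg.loci:
                if g.call(l.name)[0] != g.call(l.name)[1]:
                    assert res.consensus.call(l.name) == g.call(l.name)


class TestReliability:
    FREQS = {1: 0.5, 2: 0.3, 3: 0.2}

    def test_zero_error_concordant_is_certain(self):
        r = locus_reliability([(1, 2)] * 4, (1, 2), self.FREQS, 0.0, 0.0)
        assert r == pytest.approx(1.0)

    def test_single_homozygous_replicate_is_uncertain(self):
        one = locus_reliability([(1, 1)], (1, 1), self.FREQS, 0.2, 0.0)
        four = locus_reliability([(1, 1)] * 4, (1, 1), self.FREQS, 0.2, 0.0)
        assert one < four <= 1.0
        assert one < 1.0

    def test_monotone_in_concordant_replicates(self):
        vals = [
            locus_reliability([(1, 1)] * k, (1, 1), self.FREQS, 0.15, 0.05)
            for k in range(1, 7)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_brute_force_posterior_oracle(self):
        # independent enumeration of the generative error process:
        # ado event x dropped-copy choice x fa event x position x artifact
        ado, fa = 0.2, 0.1
        universe = (1, 2, 3)
        obs = [(1, 1), (1, 2), (1, 2)]

        def obs_prob(truth, call):
            a, b = truth
            outcomes = {}
            stage1 = (
                [(truth, 1 - ado), ((a, a), ado / 2), ((b, b), ado / 2)]
                if a != b
                else [(truth, 1.0)]
            )
            for mid, p1 in stage1:
                outcomes[canonical(mid)] = outcomes.get(canonical(mid), 0) + p1 * (1 - fa)
                spare = [u for u in universe if u not in mid]
                for pos in range(2):
                    for u in spare:
                        alt = list(mid)
                        alt[pos] = u
                        k = canonical(alt)
                        outcomes[k] = outcomes.get(k, 0) + p1 * fa / (
                            2 * len(spare)
                        )
                if not spare:
                    outcomes[canonical(mid)] = outcomes.get(canonical(mid), 0) + p1 * fa
            return outcomes.get(canonical(call), 0.0)

        posts = {}
        for g in itertools.combinations_with_replacement(universe, 2):
            prior = (
                self.FREQS[g[0]] ** 2
                if g[0] == g[1]
                else 2 * self.FREQS[g[0]] * self.FREQS[g[1]]
            )
            lik = prior
            for call in obs:
                lik *= obs_prob(g, call)
            posts[g] = lik
        expected = posts[(1, 2)] / sum(posts.values())
        got = locus_reliability(obs, (1, 2), self.FREQS, ado, fa, universe)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_multilocus_product_and_missing_rates_error(self):
        rs = ReplicateSet(
            sample_id="s",
            replicates=[{"LA": (1, 2), "LB": (1, 1)}] * 4,
        )
        consensus = MultilocusGenotype(
            sample_id="s", calls={"LA": (1, 2), "LB": (1, 1)}
        )
        freqs = {"LA": self.FREQS, "LB": self.FREQS}
        rel, per = genotype_reliability(
            rs, consensus, freqs, {"LA": (0.1, 0.0), "LB": (0.1, 0.0)}
        )
        assert rel == pytest.approx(per["LA"] * per["LB"])
        with pytest.raises(KeyError, match="LB"):
            genotype_reliability(rs, consensus, freqs, {"LA": (0.1, 0.0)})


def _qc_config(cfg, table, **kw):
    loci = cfg.locus_names
    freqs = {lo: sp.allele_frequencies(table, lo) for lo in loci}
    rates = {lo: (cfg.locus(lo).ado, cfg.locus(lo).fa) for lo in loci}
    uni = {lo: cfg.locus(lo).alleles for lo in loci}
    return QCConfig(
        freqs_by_locus=freqs, rates=rates, universe_by_locus=uni, loci=loci,
        **kw,
    )


class TestQCLoop:
    def test_clean_sample_accepted_first_round(self, abb_cfg, abb_table):
        cfg = replace(
            abb_cfg,
            loci=tuple(replace(l, ado=0.0, fa=0.0) for l in abb_cfg.loci),
            missing_rate=0.0,
        )
        t = sp.sample_population(cfg)
        qcfg = _qc_config(cfg, t)
        res = qc_loop(sp.amplify_replicates(t.individuals[0], cfg), qcfg)
        assert res.status is ConsensusStatus.ACCEPTED
        assert res.rounds_used == 0
        assert res.reliability == pytest.approx(1.0)

    def test_high_ado_no_rounds_discarded(self, abb_table):
        cfg = SimulationConfig(
            loci=(
                SimLocus(name="LA", alleles=(1, 2), frequencies=(0.5, 0.5),
                         ado=0.95),
            ),
            n_individuals=4, sib_family_fraction=0.0, missing_rate=0.0, seed=13,
        )
        t = sp.sample_population(cfg)
        het = next(
            g for g in t.individuals if len(set(g.call("LA"))) == 2
        )
        qcfg = QCConfig(
            freqs_by_locus={"LA": {1: 0.5, 2: 0.5}},
            rates={"LA": (0.95, 0.0)},
            universe_by_locus={"LA": (1, 2)},
            loci=["LA"],
            max_rounds=0,
        )
        res = qc_loop(sp.amplify_replicates(het, cfg), qcfg)
        assert res.status is ConsensusStatus.DISCARDED

    def test_mixture_detected(self, abb_cfg, abb_table):
        qcfg = _qc_config(abb_cfg, abb_table)
        mix = sp.make_mixture(
            abb_table.individuals[0], abb_table.individuals[1],
            loci=abb_cfg.locus_names,
        )
        res = qc_loop(mix, qcfg)
        assert res.status is ConsensusStatus.MIXED

    def test_acceptance_monotone_in_rounds(self, abb_cfg):
        # allowing more re-amplification rounds can only help
        cfg = replace(abb_cfg, missing_rate=0.15)
        t = sp.sample_population(cfg)
        samples = t.individuals[:30]
        rates = {}
        for k in (0, 1, 2):
            qcfg = _qc_config(cfg, t, max_rounds=k)
            accepted = 0
            for i, g in enumerate(samples):
                fetch_rng = np.random.default_rng(1000 + i)

                def fetch(loci, n):
                    return sp.amplify_replicates(
                        g, cfg, rng=fetch_rng, n_replicates=n, loci=loci
                    ).replicates

                res = qc_loop(sp.amplify_replicates(g, cfg), qcfg, fetch)
                accepted += res.status is ConsensusStatus.ACCEPTED
            rates[k] = accepted
        assert rates[0] <= rates[1] <= rates[2]


class TestForeignAlleles:
    def test_no_flags_within_universe(self, abb_cfg, abb_table):
        uni = {l.name: l.alleles for l in abb_cfg.loci}
        rs = sp.amplify_replicates(abb_table.individuals[0], abb_cfg)
        assert sp.detect_foreign_alleles(rs, uni) == []

    def test_out_of_universe_flagged(self):
        flags = sp.detect_foreign_alleles(
            rset("s", [(132, 145)], locus="CXX20"),
            {"CXX20": (132, 134, 136)},
        )
        assert [(f.locus, f.allele, f.replicate) for f in flags] == [
            ("CXX20", 145, 1)
        ]

    def test_cross_species_mixture_flagged_at_canid_loci_only(self, abb_cfg,
                                                              abb_table):
        # a bear genotype mixed with foreign DNA carrying off-universe
        # alleles at the two canid loci
        bear = abb_table.individuals[0]
        foreign_calls = dict(bear.calls)
        foreign_calls["CXX20"] = (160, 162)
        foreign_calls["REN144A06"] = (150, 152)
        foreign = MultilocusGenotype(sample_id="dog", calls=foreign_calls)
        mix = sp.make_mixture(bear, foreign, loci=abb_cfg.locus_names)
        uni = {l.name: l.alleles for l in abb_cfg.loci}
        flags = sp.detect_foreign_alleles(mix, uni)
        assert {f.locus for f in flags} == {"CXX20", "REN144A06"}


class TestNullAlleles:
    def test_estimators_on_reference_values(self):
        from strpanel.error_qc import null_allele_estimates

        r_c, r_b = null_allele_estimates(he=0.456, ho=0.333)
        assert r_c == pytest.approx(0.156, abs=5e-4)
        assert r_b == pytest.approx(0.084, abs=5e-4)
        assert null_allele_estimates(0.4, 0.4) == (0.0, 0.0)
        assert null_allele_estimates(0.0, 0.0) == (0.0, 0.0)

    def test_check_on_table(self):
        t = GenotypeTable(
            loci=[LocusDefinition(name="LA")],
            individuals=[
                MultilocusGenotype(sample_id=f"s{i}", calls={"LA": c})
                for i, c in enumerate(
                    [(1, 1)] * 40 + [(1, 2)] * 20 + [(2, 2)] * 10
                )
            ],
        )
        res = null_allele_check(t, "LA")
        assert res.p_homozygote_excess < 0.05
        assert res.chakraborty > 0 and res.brookfield1 > 0

    def test_true_null_allele_recovered(self):
        # a hidden allele at frequency 0.1: heterozygote carriers appear as
        # false homozygotes; Brookfield's estimator recovers ~0.1 on average
        r_null, n_rep, n = 0.1, 50, 400
        ests = []
        vis = np.array([0.55, 0.35, r_null])
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            inds = []
            for i in range(n):
                g = tuple(sorted(rng.choice(3, size=2, p=vis)))
                if g == (2, 2):
                    continue  # null homozygote: amplification failure
                apparent = tuple(100 + 2 * a for a in g if a != 2)
                if len(apparent) == 1:
                    apparent = apparent * 2
                inds.append(
                    MultilocusGenotype(sample_id=f"s{i}", calls={"LA": apparent})
                )
            t = GenotypeTable(loci=[LocusDefinition(name="LA")], individuals=inds)
            ests.append(null_allele_check(t, "LA").brookfield1)
        assert np.mean(ests) == pytest.approx(r_null, abs=0.05)
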