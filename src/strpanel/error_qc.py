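"""Replicate-based genotyping QC for non-invasive samples.

Non-invasive extracts (hair, feces) carry little, degraded DNA, so each
sample is amplified several times independently (the multiple-tubes
approach) and the per-locus calls are combined into a consensus genotype.
This module estimates allelic-dropout (ADO) and false-allele (FA) rates
from replicate agreement, scores the posterior reliability of a consensus
genotype under the ADO/FA observation model, and drives the accept /
re-amplify / discard quality-control loop with a 95% confidence target.
Samples showing more than two alleles in a single amplification are flagged
as mixtures; alleles outside the known population universe flag foreign
(cross-species) DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations_with_replacement
from typing import Callable, Mapping, Sequence

import numpy as np

from .diversity import hwe_exact_test, _genotype_counts
from .genotypes import (
    MISSING,
    AlleleFrequencies,
    EstimationError,
    GenotypeTable,
    MultilocusGenotype,
    ReplicateSet,
    allele_frequencies,
    canonical,
)
from .simulate import replicate_call_distribution

__all__ = [
    "ErrorRates",
    "ConsensusRule",
    "ConsensusStatus",
    "ConsensusResult",
    "QCConfig",
    "estimate_error_rates",
    "consensus_genotype",
    "genotype_reliability",
    "locus_reliability",
    "qc_loop",
    "detect_foreign_alleles",
    "null_allele_check",
    "null_allele_estimates",
    "NullAlleleResult",
]


@dataclass
class ErrorRates:
    """Per-locus replicate error rates in the GIMLET counting convention.

    ``ado`` is None (not 0) when no sample had a heterozygous consensus at
    the locus, i.e. the rate is undefined rather than observed to be zero.
    """

    locus: str
    ado: "float | None"
    fa: float
    n_het_amplifications: int  # positive replicates of het-consensus samples
    n_amplifications: int  # all positive replicates


def _rates_lookup(rates) -> dict:
    if isinstance(rates, Mapping):
        return {
            k: (v if isinstance(v, tuple) else (v.ado, v.fa))
            for k, v in rates.items()
        }
    return {r.locus: (r.ado, r.fa) for r in rates}


def estimate_error_rates(
    replicate_sets: Sequence[ReplicateSet],
    consensus_genotypes: Mapping[str, MultilocusGenotype],
    loci: "Sequence[str] | None" = None,
) -> list:
    """Count ADO and FA events against per-sample consensus genotypes.

    ADO: among positive replicates of samples whose consensus is
    heterozygous at the locus, the fraction showing exactly one of the two
    consensus alleles.  FA: among all positive replicates of samples with a
    consensus at the locus, the fraction showing at least one allele absent
    from the consensus.  Counting is exact, so replicating the input data
    leaves the rates unchanged.
    """
    if loci is None:
        seen: list = []
        for rs in replicate_sets:
            for rep in rs.replicates:
                for lo in rep:
                    if lo not in seen:
                        seen.append(lo)
        loci = seen

    out = []
    for locus in loci:
        ado_num = ado_den = fa_num = fa_den = 0
        for rs in replicate_sets:
            cons = consensus_genotypes.get(rs.sample_id)
            if cons is None:
                continue
            cc = cons.call(locus)
            if cc is MISSING:
                continue
            cons_alleles = set(cc)
            het = len(cons_alleles) == 2
            for call in rs.positive_calls(locus):
                fa_den += 1
                if set(call) - cons_alleles:
                    fa_num += 1
                if het:
                    ado_den += 1
                    # a dropout manifests as a false homozygote for one of
                    # the two consensus alleles
                    s = set(call)
                    if len(s) == 1 and s <= cons_alleles:
                        ado_num += 1
        out.append(
            ErrorRates(
                locus=locus,
                ado=(ado_num / ado_den) if ado_den else None,
                fa=(fa_num / fa_den) if fa_den else 0.0,
                n_het_amplifications=ado_den,
                n_amplifications=fa_den,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Consensus calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusRule:
    """Multiple-tubes acceptance thresholds.

    A heterozygote needs each allele observed in at least
    ``min_het_observations`` replicates; a homozygote needs at least
    ``min_hom_replicates`` concordant homozygous replicates with no second
    allele ever seen.
    """

    min_het_observations: int = 2
    min_hom_replicates: int = 3


class ConsensusStatus(str, Enum):
    ACCEPTED = "accepted"
    NEEDS_REPLICATES = "needs_replicates"
    DISCARDED = "discarded"
    MIXED = "mixed"


@dataclass
class ConsensusResult:
    sample_id: str
    consensus: MultilocusGenotype
    support: dict  # locus -> {allele: replicate count}
    unresolved_loci: list
    status: ConsensusStatus
    reliability: "float | None" = None
    per_locus_reliability: dict = field(default_factory=dict)
    mixed_loci: list = field(default_factory=list)
    rounds_used: int = 0


def _mixture_loci(rset: ReplicateSet, loci) -> list:
    out = []
    for locus in loci:
        if any(len(set(c)) > 2 for c in rset.positive_calls(locus)):
            out.append(locus)
    return out


def consensus_genotype(
    rset: ReplicateSet,
    rule: ConsensusRule = ConsensusRule(),
    loci: "Sequence[str] | None" = None,
) -> ConsensusResult:
    """Combine a sample's PCR replicates into a consensus genotype.

    Loci satisfying neither the heterozygote nor the homozygote rule are
    left MISSING and listed in ``unresolved_loci``.  More than two distinct
    alleles in any single replicate marks the sample as a mixture.
    """
    if loci is None:
        seen: list = []
        for rep in rset.replicates:
            for lo in rep:
                if lo not in seen:
                    seen.append(lo)
        loci = seen

    calls: dict = {}
    support: dict = {}
    unresolved: list = []
    for locus in loci:
        pos = rset.positive_calls(locus)
        sup: dict = {}
        for call in pos:
            for a in set(call):
                sup[a] = sup.get(a, 0) + 1
        support[locus] = sup
        if not pos:
            calls[locus] = MISSING
            continue
        well = sorted(a for a, k in sup.items() if k >= rule.min_het_observations)
        if len(well) == 2:
            calls[locus] = canonical(well)
            continue
        n_hom = sum(1 for c in pos if len(set(c)) == 1)
        if len(sup) == 1 and n_hom >= rule.min_hom_replicates:
            a = next(iter(sup))
            calls[locus] = canonical((a, a))
            continue
        calls[locus] = MISSING
        unresolved.append(locus)

    mixed = _mixture_loci(rset, loci)
    status = (
        ConsensusStatus.MIXED
        if mixed
        else (
            ConsensusStatus.NEEDS_REPLICATES
            if unresolved
            else ConsensusStatus.ACCEPTED
        )
    )
    return ConsensusResult(
        sample_id=rset.sample_id,
        consensus=MultilocusGenotype(sample_id=rset.sample_id, calls=calls),
        support=support,
        unresolved_loci=unresolved,
        status=status,
        mixed_loci=mixed,
    )


# ---------------------------------------------------------------------------
# Reliability (Bayesian re-specification of the published approach)
# ---------------------------------------------------------------------------


def _hwe_prior(g: tuple, freqs: dict) -> float:
    a, b = g
    return freqs[a] ** 2 if a == b else 2.0 * freqs[a] * freqs[b]


def locus_reliability(
    observed_calls: Sequence,
    consensus_call: tuple,
    freqs: Mapping[int, float],
    ado: float,
    fa: float,
    universe: "Sequence[int] | None" = None,
) -> float:
    """Posterior probability that ``consensus_call`` is the true genotype.

    The prior over true genotypes is the HWE genotype distribution from the
    population allele frequencies; the likelihood of the observed positive
    replicate calls follows the ADO/FA observation model shared with the
    synthetic generator.  Replicates observed with more than two alleles
    have zero likelihood under every single-source genotype, driving the
    posterior (and hence the sample's reliability) to zero.
    """
    if universe is None:
        universe = sorted(freqs)
    calls = [c for c in observed_calls if c is not MISSING]
    candidates = list(combinations_with_replacement(sorted(freqs), 2))
    post = np.zeros(len(candidates))
    dists = {}
    for i, g in enumerate(candidates):
        prior = _hwe_prior(canonical(g), freqs)
        if prior == 0.0:
            continue
        dist = dists.get(g)
        if dist is None:
            dist = dists[g] = replicate_call_distribution(
                canonical(g), ado, fa, universe
            )
        lik = prior
        for call in calls:
            lik *= dist.get(call, 0.0)
            if lik == 0.0:
                break
        post[i] = lik
    total = post.sum()
    if total == 0.0:
        return 0.0
    target = canonical(consensus_call)
    for i, g in enumerate(candidates):
        if canonical(g) == target:
            return float(post[i] / total)
    return 0.0


def genotype_reliability(
    rset: ReplicateSet,
    consensus: MultilocusGenotype,
    freqs_by_locus: Mapping[str, "AlleleFrequencies | Mapping[int, float]"],
    rates,
    universe_by_locus: "Mapping[str, Sequence[int]] | None" = None,
    loci: "Sequence[str] | None" = None,
) -> tuple[float, dict]:
    """Multilocus reliability: product of per-locus posteriors.

    Loci where the consensus is MISSING contribute nothing (they carry no
    call to be right or wrong about).  ``loci`` restricts the calculation
    (e.g. to the autosomal panel, leaving a sex marker out); by default all
    consensus-called loci enter, and rates or frequencies missing for any of
    them raise an error naming the locus.
    """
    lookup = _rates_lookup(rates)
    per_locus: dict = {}
    overall = 1.0
    scope = None if loci is None else set(loci)
    for locus, cons_call in consensus.calls.items():
        if cons_call is MISSING or (scope is not None and locus not in scope):
            continue
        if locus not in lookup:
            raise KeyError(f"no error rates for locus {locus!r}")
        if locus not in freqs_by_locus:
            raise KeyError(f"no allele frequencies for locus {locus!r}")
        fr = freqs_by_locus[locus]
        freqs = fr.freqs if isinstance(fr, AlleleFrequencies) else dict(fr)
        ado, fa = lookup[locus]
        r = locus_reliability(
            rset.positive_calls(locus),
            cons_call,
            freqs,
            ado if ado is not None else 0.0,
            fa,
            universe=None if universe_by_locus is None
            else universe_by_locus.get(locus),
        )
        per_locus[locus] = r
        overall *= r
    return overall, per_locus


# ---------------------------------------------------------------------------
# QC loop
# ---------------------------------------------------------------------------


@dataclass
class QCConfig:
    """Parameters of the accept / re-amplify / discard loop."""

    freqs_by_locus: Mapping
    rates: object  # list of ErrorRates or mapping locus -> (ado, fa)
    confidence: float = 0.95
    max_rounds: int = 2
    replicates_per_round: int = 2
    rule: ConsensusRule = field(default_factory=ConsensusRule)
    universe_by_locus: "Mapping | None" = None
    loci: "Sequence[str] | None" = None  # reliability scope (e.g. autosomal)


def qc_loop(
    rset: ReplicateSet,
    config: QCConfig,
    fetch_more: "Callable[[list, int], list] | None" = None,
) -> ConsensusResult:
    """Iterate consensus -> reliability until acceptance, more PCRs, or discard.

    Each round builds the consensus and computes its reliability; at or above
    ``confidence`` (and with every locus resolved) the genotype is accepted.
    Otherwise ``fetch_more(loci, n)`` is asked for ``n`` additional replicate
    calls at the under-performing loci (unresolved loci plus those whose
    per-locus posterior falls below the per-locus share of the confidence
    target), up to ``max_rounds`` times; failing that the sample is
    discarded.  A mixture signature (3+ alleles in one amplification) stops
    the loop immediately with status ``mixed``.
    """
    work = ReplicateSet(
        sample_id=rset.sample_id,
        replicates=[dict(r) for r in rset.replicates],
        lab=rset.lab,
    )
    loci = list(dict.fromkeys(lo for rep in work.replicates for lo in rep))

    for round_no in range(config.max_rounds + 1):
        res = consensus_genotype(work, rule=config.rule, loci=loci)
        res.rounds_used = round_no
        if res.status is ConsensusStatus.MIXED:
            return res
        rel, per_locus = genotype_reliability(
            work,
            res.consensus,
            config.freqs_by_locus,
            config.rates,
            universe_by_locus=config.universe_by_locus,
            loci=config.loci,
        )
        res.reliability = rel
        res.per_locus_reliability = per_locus
        unresolved = [
            lo
            for lo in res.unresolved_loci
            if config.loci is None or lo in config.loci
        ]
        n_called = max(1, len(per_locus))
        per_locus_target = config.confidence ** (1.0 / n_called)
        weak = sorted(
            set(unresolved)
            | {lo for lo, r in per_locus.items() if r < per_locus_target}
        )
        if rel >= config.confidence and not unresolved:
            res.status = ConsensusStatus.ACCEPTED
            return res
        if round_no == config.max_rounds or fetch_more is None:
            res.status = ConsensusStatus.DISCARDED
            return res
        extra = fetch_more(weak or loci, config.replicates_per_round)
        for rep in extra:
            work.replicates.append(dict(rep))
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Foreign alleles and null alleles
# ---------------------------------------------------------------------------


@dataclass
class ForeignAlleleFlag:
    sample_id: str
    locus: str
    allele: int
    replicate: "int | None" = None  # 1-based; None for a consensus genotype


def detect_foreign_alleles(
    data: "ReplicateSet | MultilocusGenotype",
    universe_by_locus: Mapping[str, Sequence[int]],
) -> list:
    """Flag alleles outside the declared population universe at any locus.

    Cross-species contamination (e.g. canid DNA on a bear hair snag) shows
    up as alleles no population member carries; such alleles repeat across
    replicates and cannot be corrected, only flagged.
    """
    flags: list = []
    if isinstance(data, ReplicateSet):
        for idx, rep in enumerate(data.replicates, start=1):
            for locus, call in rep.items():
                if call is MISSING or locus not in universe_by_locus:
                    continue
                uni = set(universe_by_locus[locus])
                for a in sorted(set(call) - uni):
                    flags.append(
                        ForeignAlleleFlag(data.sample_id, locus, a, idx)
                    )
    else:
        for locus, call in data.calls.items():
            if call is MISSING or locus not in universe_by_locus:
                continue
            uni = set(universe_by_locus[locus])
            for a in sorted(set(call) - uni):
                flags.append(ForeignAlleleFlag(data.sample_id, locus, a))
    return flags


def null_allele_estimates(he: float, ho: float) -> tuple[float, float]:
    """Moment estimators of null-allele frequency from a heterozygote deficit.

    Chakraborty: r = (He - Ho) / (He + Ho); Brookfield's first estimator:
    r = (He - Ho) / (1 + He).  Both are 0 when He = Ho = 0.
    """
    if he + ho == 0.0:
        return 0.0, 0.0
    return (he - ho) / (he + ho), (he - ho) / (1.0 + he)


@dataclass
class NullAlleleResult:
    locus: str
    p_homozygote_excess: float
    chakraborty: float  # r = (He - Ho) / (He + Ho)
    brookfield1: float  # r = (He - Ho) / (1 + He)
    he: float
    ho: float


def null_allele_check(table: GenotypeTable, locus: str) -> NullAlleleResult:
    """Screen a locus for null alleles via homozygote excess.

    Returns the one-sided exact HWE tail toward heterozygote deficiency and
    the two moment estimators of null-allele frequency (Chakraborty and
    Brookfield's first estimator).  Both estimators are defined as 0 when
    He = Ho = 0.
    """
    freqs = allele_frequencies(table, locus)
    p = freqs.vector()
    if len(p) < 2:
        raise EstimationError(f"{locus}: null-allele check needs >= 2 alleles")
    he = 1.0 - float(np.sum(p**2))
    n_typed, n_het, counts = _genotype_counts(table, locus)
    ho = n_het / n_typed
    chak, brook = null_allele_estimates(he, ho)
    return NullAlleleResult(
        locus=locus,
        p_homozygote_excess=hwe_exact_test(counts, statistic="het_deficit"),
        chakraborty=chak,
        brookfield1=brook,
        he=he,
        ho=ho,
    )
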