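"""Discriminatory power of STR panels: probability of identity and mismatches.

The probability of identity at one locus is the chance that two random
individuals share a genotype under HWE:

    P_ID     = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2

and for full siblings (the conservative upper bound used to size panels for
populations with family structure):

    P_IDsib  = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4

Multilocus values are products across loci under independence.  Panels are
compared by ranking loci from most to least informative (lowest per-locus
P_ID first) and accumulating the product until it crosses a decision
threshold.  The expected number of loci at which two profiles differ is a
Poisson-binomial distribution over per-locus match probabilities, computed
by dynamic-programming convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import (
    AlleleFrequencies,
    GenotypeTable,
    allele_frequencies,
    count_mismatches,
)

__all__ = [
    "IdentityProfile",
    "MismatchReport",
    "UNREACHABLE",
    "pid_locus",
    "pidsib_locus",
    "rank_loci",
    "multilocus_identity",
    "loci_needed",
    "identity_profile",
    "observed_mismatch_distribution",
    "expected_mismatch_distribution",
]

#: Sentinel returned by :func:`loci_needed` when no prefix of the ranked
#: loci reaches the requested threshold.
UNREACHABLE = -1


def _freq_vector(freqs) -> np.ndarray:
    if isinstance(freqs, AlleleFrequencies):
        p = freqs.vector()
    else:
        p = np.asarray(
            list(freqs.values()) if isinstance(freqs, Mapping) else freqs,
            dtype=float,
        )
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def pid_locus(freqs) -> float:
    """Probability two unrelated HWE individuals match at this locus."""
    p = _freq_vector(freqs)
    sum2 = float(np.sum(p**2))
    sum4 = float(np.sum(p**4))
    # sum_i p^4 + sum_{i<j} (2 p_i p_j)^2  ==  2 (sum p^2)^2 - sum p^4
    return 2.0 * sum2**2 - sum4


def pidsib_locus(freqs) -> float:
    """Probability two full siblings match at this locus (upper bound form)."""
    p = _freq_vector(freqs)
    sum2 = float(np.sum(p**2))
    sum4 = float(np.sum(p**4))
    return 0.25 + 0.5 * sum2 + 0.5 * sum2**2 - 0.25 * sum4


def rank_loci(
    pid_by_locus: Mapping[str, float],
    he_by_locus: "Mapping[str, float] | None" = None,
) -> list:
    """Order loci from most to least informative (ascending per-locus P_ID).

    Ties break by descending He when supplied, then by locus name.
    """
    if not pid_by_locus:
        raise ValueError("no loci to rank")
    he = he_by_locus or {}
    return sorted(
        pid_by_locus,
        key=lambda lo: (pid_by_locus[lo], -he.get(lo, 0.0), lo),
    )


def multilocus_identity(
    profiles: Mapping[str, float], locus_set: Sequence[str]
) -> float:
    """Product of per-locus match probabilities over a panel."""
    if not locus_set:
        raise ValueError("empty locus set")
    out = 1.0
    for lo in locus_set:
        if lo not in profiles:
            raise KeyError(f"unknown locus {lo!r}")
        out *= profiles[lo]
    return out


def loci_needed(
    profiles: Mapping[str, float],
    threshold: float,
    ranking: "Sequence[str] | None" = None,
) -> int:
    """Smallest number of ranked loci whose cumulative product is < threshold.

    ``profiles`` maps locus to the per-locus match probability of the chosen
    estimator (unrelated P_ID or sibling P_IDsib).  Loci are accumulated
    most-informative-first (by the profile itself unless ``ranking`` is
    given).  Returns :data:`UNREACHABLE` when even the full panel does not
    cross the threshold; comparison is strict (<).
    """
    if not 0.0 < threshold < 1.0 and threshold != 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    order = list(ranking) if ranking is not None else rank_loci(profiles)
    prod = 1.0
    for k, lo in enumerate(order, start=1):
        prod *= profiles[lo]
        if prod < threshold:
            return k
    return UNREACHABLE


@dataclass
class IdentityProfile:
    """Per-locus and accumulated identity probabilities for a panel."""

    pid: dict  # locus -> P_ID
    pidsib: dict  # locus -> P_IDsib
    ranking: list  # most informative first
    cumulative_pid: list  # product over first k ranked loci, k = 1..L
    cumulative_pidsib: list


def identity_profile(
    table: GenotypeTable, loci: "Sequence[str] | None" = None
) -> IdentityProfile:
    """Compute the full identity profile of a genotype table's panel."""
    if loci is None:
        loci = [l.name for l in table.autosomal_loci]
    pid, pidsib, he = {}, {}, {}
    for lo in loci:
        fr = allele_frequencies(table, lo)
        pid[lo] = pid_locus(fr)
        pidsib[lo] = pidsib_locus(fr)
        he[lo] = 1.0 - float(np.sum(fr.vector() ** 2))
    ranking = rank_loci(pid, he)
    cum_pid, cum_sib = [], []
    p = s = 1.0
    for lo in ranking:
        p *= pid[lo]
        s *= pidsib[lo]
        cum_pid.append(p)
        cum_sib.append(s)
    return IdentityProfile(
        pid=pid, pidsib=pidsib, ranking=ranking,
        cumulative_pid=cum_pid, cumulative_pidsib=cum_sib,
    )


# ---------------------------------------------------------------------------
# Observed mismatch distribution
# ---------------------------------------------------------------------------


@dataclass
class MismatchReport:
    """Histogram of pairwise mismatch counts over a panel.

    ``pair_counts[m]`` is the number of genotype pairs differing at exactly
    ``m`` compared loci.  ``unique_at[t]`` is the number of individuals whose
    genotype differs from every other individual at more than ``t`` loci
    (individuals that remain unambiguously identifiable if up to ``t``
    locus differences are attributed to genotyping error).
    ``convention`` is one of ``unordered`` (n(n-1)/2 distinct pairs,
    default), ``ordered`` (n(n-1)), or ``squared`` (n^2: ordered pairs plus
    self-pairs, self-pairs not tallied in the histogram) — the latter two
    for compatibility with reports quoting n^2 totals.
    """

    pair_counts: dict
    unique_at: dict
    n_individuals: int
    convention: str = "unordered"
    total_pairs: int = 0
    min_mismatch: dict = field(default_factory=dict)  # sample_id -> min MM

    def pairs_at(self, m: int) -> int:
        return self.pair_counts.get(m, 0)


def observed_mismatch_distribution(
    table: GenotypeTable,
    locus_set: "Sequence[str] | None" = None,
    convention: str = "unordered",
    max_threshold: int = 3,
    strict_missing: bool = False,
) -> MismatchReport:
    """Count pairwise locus mismatches between all genotypes over a panel.

    Loci where either genotype is MISSING are excluded pair-wise (see
    :func:`strpanel.genotypes.count_mismatches`).
    """
    if convention not in ("unordered", "ordered", "squared"):
        raise ValueError(f"unknown pair convention {convention!r}")
    if locus_set is None:
        locus_set = [l.name for l in table.autosomal_loci]
    inds = table.individuals
    n = len(inds)
    if n < 2:
        raise ValueError("need at least two individuals")

    mult = 1 if convention == "unordered" else 2
    pair_counts: dict = {}
    min_mm = {g.sample_id: None for g in inds}
    for i in range(n):
        for j in range(i + 1, n):
            mm, comp, _ = count_mismatches(
                inds[i], inds[j], locus_set, strict_missing=strict_missing
            )
            if comp == 0:
                continue
            pair_counts[mm] = pair_counts.get(mm, 0) + mult
            for sid in (inds[i].sample_id, inds[j].sample_id):
                if min_mm[sid] is None or mm < min_mm[sid]:
                    min_mm[sid] = mm

    if convention == "squared":
        total = n * n
    elif convention == "ordered":
        total = n * (n - 1)
    else:
        total = n * (n - 1) // 2

    unique_at = {}
    for t in range(max_threshold + 1):
        unique_at[t] = sum(
            1 for sid, m in min_mm.items() if m is not None and m > t
        )
    return MismatchReport(
        pair_counts=pair_counts,
        unique_at=unique_at,
        n_individuals=n,
        convention=convention,
        total_pairs=total,
        min_mismatch=min_mm,
    )


# ---------------------------------------------------------------------------
# Expected mismatch distribution (Poisson binomial)
# ---------------------------------------------------------------------------


def expected_mismatch_distribution(match_probs: Sequence[float]) -> np.ndarray:
    """Distribution of the number of mismatching loci between two profiles.

    ``match_probs`` holds the per-locus probability that two individuals
    match (per-locus P_ID for unrelated pairs, P_IDsib for sib pairs); locus
    ``i`` mismatches with probability 1 - match_probs[i] independently.
    Returns the Poisson-binomial pmf over 0..L mismatches via DP
    convolution; sums to 1 within 1e-12.
    """
    q = np.asarray(match_probs, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("match probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for m in q:
        miss = 1.0 - m
        new = np.zeros(len(pmf) + 1)
        new[:-1] += pmf * m
        new[1:] += pmf * miss
        pmf = new
    assert abs(pmf.sum() - 1.0) < 1e-12
    return pmf
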