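"""Per-locus diversity statistics, exact HWE testing, and F-statistics.

Definitions (p = allele relative frequencies at a locus, n = typed
individuals):

* He  = 1 - sum(p^2)            expected heterozygosity (uncorrected)
* uHe = 2n/(2n-1) * He          unbiased expected heterozygosity
* Ne  = 1 / sum(p^2)            effective number of alleles
* I   = -sum(p * ln p)          Shannon information index
* Ho  = heterozygote fraction among typed individuals

The Hardy-Weinberg test is the exact conditional test: given the allele
counts, genotype arrays are enumerated (complete enumeration up to four
alleles where feasible) and the two-sided p-value is the total probability
of arrays no more probable than the observed one.  F-statistics are the
Weir & Cockerham (1984) variance-component estimators with a leave-one-
locus-out jackknife for the multilocus mean and SE; negative estimates are
reported as computed, never truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .genotypes import (
    MISSING,
    AlleleFrequencies,
    EstimationError,
    GenotypeTable,
    allele_frequencies,
)

__all__ = [
    "LocusSummary",
    "FStatRow",
    "JackknifeSummary",
    "locus_summary",
    "summarize_loci",
    "hwe_test",
    "hwe_exact_test",
    "private_alleles",
    "wc_fstats",
]


@dataclass
class LocusSummary:
    locus: str
    A: int
    Ne: float
    Ho: float
    He: float
    uHe: float
    I: float
    hwe_p: float
    n_typed: int


@dataclass
class FStatRow:
    locus: str
    fis: float
    fit: float
    fst: float


@dataclass
class JackknifeSummary:
    """Multilocus F-statistics with leave-one-locus-out jackknife errors."""

    fis: float
    fit: float
    fst: float
    fis_se: float
    fit_se: float
    fst_se: float


# ---------------------------------------------------------------------------
# Per-locus summary
# ---------------------------------------------------------------------------


def _genotype_counts(table: GenotypeTable, locus: str, group=None):
    """(n_typed, n_het, genotype count dict) at a locus."""
    n_typed = n_het = 0
    counts: dict = {}
    for g in table.individuals:
        if group is not None and table.groups.get(g.sample_id) != group:
            continue
        c = g.call(locus)
        if c is MISSING:
            continue
        n_typed += 1
        if c[0] != c[1]:
            n_het += 1
        counts[c] = counts.get(c, 0) + 1
    return n_typed, n_het, counts


def locus_summary(
    table: GenotypeTable, locus: str, group: str | None = None
) -> LocusSummary:
    """All standard diversity statistics for one locus."""
    freqs = allele_frequencies(table, locus, group=group)
    n_typed, n_het, _ = _genotype_counts(table, locus, group)
    p = freqs.vector()
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    ne = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    uhe = he * (2 * n_typed) / (2 * n_typed - 1) if n_typed > 1 else he
    return LocusSummary(
        locus=locus,
        A=len(p),
        Ne=ne,
        Ho=n_het / n_typed,
        He=he,
        uHe=uhe,
        I=shannon,
        hwe_p=hwe_test(table, locus, group=group),
        n_typed=n_typed,
    )


def summarize_loci(table: GenotypeTable, loci=None, group=None) -> list:
    if loci is None:
        loci = [l.name for l in table.autosomal_loci]
    return [locus_summary(table, lo, group=group) for lo in loci]


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def _log_array_prob(genotype_counts: dict, allele_counts: dict, n: int) -> float:
    """log conditional probability of a genotype array given allele counts."""
    two_n = sum(allele_counts.values())
    n_het = sum(v for g, v in genotype_counts.items() if g[0] != g[1])
    lp = (
        gammaln(n + 1)
        + n_het * np.log(2.0)
        + sum(gammaln(a + 1) for a in allele_counts.values())
        - gammaln(two_n + 1)
        - sum(gammaln(v + 1) for v in genotype_counts.values())
    )
    return float(lp)


def _enumerate_arrays(allele_counts: dict):
    """Yield (genotype_counts, logP) for every array with these allele counts."""
    alleles = sorted(allele_counts)
    het_pairs = list(combinations(alleles, 2))
    n = sum(allele_counts.values()) // 2

    def rec(idx, remaining, het_counts):
        if idx == len(het_pairs):
            gc = dict(het_counts)
            ok = True
            for a in alleles:
                r = remaining[a]
                if r < 0 or r % 2:
                    ok = False
                    break
                if r:
                    gc[(a, a)] = r // 2
            if ok:
                yield gc
            return
        a, b = het_pairs[idx]
        cap = min(remaining[a], remaining[b])
        for f in range(cap + 1):
            if f:
                het_counts[(a, b)] = f
            elif (a, b) in het_counts:
                del het_counts[(a, b)]
            remaining[a] -= f
            remaining[b] -= f
            yield from rec(idx + 1, remaining, het_counts)
            remaining[a] += f
            remaining[b] += f
        het_counts.pop((a, b), None)

    for gc in rec(0, dict(allele_counts), {}):
        yield gc, _log_array_prob(gc, allele_counts, n)


def _enumeration_cost(allele_counts: dict) -> float:
    alleles = sorted(allele_counts)
    cost = 1.0
    for a, b in combinations(alleles, 2):
        cost *= min(allele_counts[a], allele_counts[b]) + 1
    return cost


def _sample_arrays(allele_counts: dict, n_draws: int, rng):
    """Sample genotype arrays from the conditional null by random gene-copy
    pairing (the distribution the exact test conditions on)."""
    copies = np.repeat(
        np.array(sorted(allele_counts)),
        [allele_counts[a] for a in sorted(allele_counts)],
    )
    n = len(copies) // 2
    for _ in range(n_draws):
        perm = rng.permutation(copies)
        gc: dict = {}
        for i in range(n):
            g = (perm[2 * i], perm[2 * i + 1])
            g = (min(g), max(g))
            gc[g] = gc.get(g, 0) + 1
        yield gc


_ENUM_LIMIT = 2_000_000


def hwe_exact_test(
    genotype_counts: dict,
    statistic: str = "prob",
    n_mc: int = 20_000,
    seed: int = 0,
) -> float:
    """Exact conditional HWE test from a genotype count dict.

    ``statistic='prob'`` gives the standard two-sided probability-ordered
    tail (arrays no more probable than the observed one).  ``'het_deficit'``
    gives the one-sided tail toward homozygote excess (arrays with no more
    heterozygotes than observed), the direction relevant to null-allele
    screening.  Falls back to conditional Monte-Carlo sampling when complete
    enumeration would be too large, and to a pooled chi-square above four
    alleles.
    """
    allele_counts: dict = {}
    for (a, b), v in genotype_counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + v
        allele_counts[b] = allele_counts.get(b, 0) + v
    if len(allele_counts) <= 1:
        return 1.0
    if len(allele_counts) > 4:
        return _hwe_chi2(genotype_counts, allele_counts)

    n = sum(genotype_counts.values())
    obs_lp = _log_array_prob(genotype_counts, allele_counts, n)
    obs_het = sum(v for g, v in genotype_counts.items() if g[0] != g[1])
    tol = 1e-9

    if _enumeration_cost(allele_counts) <= _ENUM_LIMIT:
        p = 0.0
        for gc, lp in _enumerate_arrays(allele_counts):
            if statistic == "prob":
                if lp <= obs_lp + tol:
                    p += np.exp(lp)
            else:
                n_het = sum(v for g, v in gc.items() if g[0] != g[1])
                if n_het <= obs_het:
                    p += np.exp(lp)
        return min(1.0, p)

    rng = np.random.default_rng(seed)
    hits = 0
    for gc in _sample_arrays(allele_counts, n_mc, rng):
        if statistic == "prob":
            if _log_array_prob(gc, allele_counts, n) <= obs_lp + tol:
                hits += 1
        else:
            n_het = sum(v for g, v in gc.items() if g[0] != g[1])
            if n_het <= obs_het:
                hits += 1
    return hits / n_mc


def _hwe_chi2(genotype_counts: dict, allele_counts: dict) -> float:
    """Chi-square HWE test with pooling of rare expected classes (A > 4)."""
    n = sum(genotype_counts.values())
    two_n = sum(allele_counts.values())
    p = {a: c / two_n for a, c in allele_counts.items()}
    alleles = sorted(allele_counts)
    expected = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            e = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            expected[(a, b)] = e
    # pool classes with expected count < 5 into one
    main = {g: e for g, e in expected.items() if e >= 5}
    pooled_e = sum(e for g, e in expected.items() if e < 5)
    pooled_o = sum(genotype_counts.get(g, 0) for g in expected if expected[g] < 5)
    chi2 = sum(
        (genotype_counts.get(g, 0) - e) ** 2 / e for g, e in main.items()
    )
    n_classes = len(main)
    if pooled_e > 0:
        chi2 += (pooled_o - pooled_e) ** 2 / pooled_e
        n_classes += 1
    df = max(1, n_classes - len(alleles))
    return float(chi2_dist.sf(chi2, df))


def hwe_test(
    table: GenotypeTable, locus: str, group: str | None = None
) -> float:
    """Exact conditional HWE p-value for a locus (1.0 when monomorphic)."""
    n_typed, _, counts = _genotype_counts(table, locus, group)
    if n_typed == 0:
        raise EstimationError(f"{locus}: no typed individuals")
    return hwe_exact_test(counts)


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------


@dataclass
class PrivateAlleleReport:
    per_locus: dict  # group -> {locus: count}
    mean: dict  # group -> mean private alleles per locus
    se: dict  # group -> standard error of that mean


def private_alleles(
    table: GenotypeTable, grouping: dict | None = None, loci=None
) -> PrivateAlleleReport:
    """Count alleles exclusive to each group, per locus.

    An allele is private to group g iff its frequency is positive in g and
    zero in every other group.  Individuals without a group label are
    ignored.
    """
    if grouping is None:
        grouping = table.groups
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("private alleles need at least two groups")
    if loci is None:
        loci = [l.name for l in table.autosomal_loci]

    observed: dict = {g: {} for g in groups}
    work = GenotypeTable(table.loci, table.individuals, dict(grouping))
    for locus in loci:
        for g in groups:
            try:
                fr = allele_frequencies(work, locus, group=g)
                observed[g][locus] = set(fr.freqs)
            except EstimationError:
                observed[g][locus] = set()

    per_locus = {g: {} for g in groups}
    for locus in loci:
        for g in groups:
            others = set().union(
                *(observed[h][locus] for h in groups if h != g)
            )
            per_locus[g][locus] = len(observed[g][locus] - others)

    mean, se = {}, {}
    for g in groups:
        vals = np.array([per_locus[g][lo] for lo in loci], dtype=float)
        mean[g] = float(vals.mean())
        se[g] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return PrivateAlleleReport(per_locus=per_locus, mean=mean, se=se)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F-statistics
# ---------------------------------------------------------------------------


def _wc_components(table: GenotypeTable, locus: str, groups: Sequence[str]):
    """Summed variance components (a, b, c) over alleles at one locus.

    Returns None when fewer than two groups have >= 2 typed individuals.
    """
    stats = []
    for g in groups:
        n_typed, _, counts = _genotype_counts(table, locus, g)
        if n_typed >= 2:
            stats.append((g, n_typed, counts))
    if len(stats) < 2:
        return None

    r = len(stats)
    n_i = np.array([s[1] for s in stats], dtype=float)
    nbar = n_i.mean()
    n_c = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)

    alleles = sorted(
        {a for _, _, counts in stats for g in counts for a in g}
    )
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.empty(r)
        h_i = np.empty(r)
        for k, (_, n, counts) in enumerate(stats):
            copies = sum(
                v * ((g[0] == allele) + (g[1] == allele)) for g, v in counts.items()
            )
            hets = sum(
                v
                for g, v in counts.items()
                if g[0] != g[1] and allele in g
            )
            p_i[k] = copies / (2 * n)
            h_i[k] = hets / n
        pbar = float(np.sum(n_i * p_i) / (r * nbar))
        s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n_i * h_i) / (r * nbar))

        a = (nbar / n_c) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _ratios(a: float, b: float, c: float):
    tot = a + b + c
    fst = a / tot if tot != 0 else 0.0
    fit = 1.0 - c / tot if tot != 0 else 0.0
    fis = 1.0 - c / (b + c) if (b + c) != 0 else 0.0
    return fis, fit, fst


def wc_fstats(
    table: GenotypeTable, grouping: dict | None = None, loci=None
) -> tuple[list, JackknifeSummary]:
    """Weir-Cockerham F-statistics per locus plus jackknifed multilocus means.

    Multilocus estimates sum the variance components across loci; the
    jackknife (leave one locus out) supplies the SE reported with the mean.
    """
    if grouping is None:
        grouping = table.groups
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("F-statistics need at least two groups")
    if loci is None:
        loci = [l.name for l in table.autosomal_loci]

    work = GenotypeTable(table.loci, table.individuals, dict(grouping))
    rows, comps, used = [], [], []
    for locus in loci:
        comp = _wc_components(work, locus, groups)
        if comp is None:
            warnings.warn(
                f"locus {locus} typed in fewer than two groups; excluded",
                stacklevel=2,
            )
            continue
        fis, fit, fst = _ratios(*comp)
        rows.append(FStatRow(locus=locus, fis=fis, fit=fit, fst=fst))
        comps.append(comp)
        used.append(locus)
    if not comps:
        raise EstimationError("no locus usable for F-statistics")

    comps_arr = np.array(comps)  # L x 3
    total = comps_arr.sum(axis=0)
    multi = _ratios(*total)

    L = len(comps)
    if L > 1:
        loo = np.array(
            [_ratios(*(total - comps_arr[i])) for i in range(L)]
        )  # L x 3 (fis, fit, fst)
        se = np.sqrt((L - 1) / L * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
    else:
        se = np.zeros(3)
    summary = JackknifeSummary(
        fis=multi[0], fit=multi[1], fst=multi[2],
        fis_se=float(se[0]), fit_se=float(se[1]), fst_se=float(se[2]),
    )
    return rows, summary
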