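"""Compare STR marker subsets and select a routine monitoring panel.

A candidate panel is scored on three axes: discriminatory power (multilocus
P_ID / P_IDsib and observed low-mismatch pair counts — too little power
underestimates population size because distinct bears collide), genotyping
error (per-locus ADO/FA — too much error overestimates it by fabricating
ghost genotypes), and fragment length (short amplicons genotype degraded
non-invasive DNA more reliably).  Selection starts from every candidate
locus, drops loci violating the per-locus error caps, and re-admits dropped
loci (most informative first) only if the sibling-identity ceiling cannot
otherwise be met.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diversity import LocusSummary, summarize_loci
from .error_qc import ErrorRates
from .genotypes import GenotypeTable
from .identity import (
    identity_profile,
    multilocus_identity,
    observed_mismatch_distribution,
)

__all__ = [
    "PanelEvaluation",
    "SelectionCriteria",
    "PanelSelection",
    "evaluate_panels",
    "select_panel",
    "report",
]


@dataclass
class PanelEvaluation:
    """Summary metrics of one marker subset, mirroring a study-style table."""

    name: str
    loci: list
    ne_mean: float
    ho_mean: float
    ho_se: float
    he_mean: float
    he_se: float
    pid: float
    pidsib: float
    mm_pairs: dict  # mismatch count -> number of pairs (0..3 at least)
    mean_ado: float
    mean_fa: float
    max_fragment_bp: "int | None"
    total_pairs: int = 0
    pair_convention: str = "unordered"


def _rates_map(error_rates) -> dict:
    if error_rates is None:
        return {}
    if isinstance(error_rates, Mapping):
        out = {}
        for k, v in error_rates.items():
            if isinstance(v, ErrorRates):
                out[k] = (v.ado, v.fa)
            else:
                out[k] = tuple(v)
        return out
    return {r.locus: (r.ado, r.fa) for r in error_rates}


def _max_fragment(table: GenotypeTable, loci) -> "int | None":
    tops = []
    for name in loci:
        ld = table.locus(name)
        if ld.size_range_by_lab:
            tops.append(max(hi for _, hi in ld.size_range_by_lab.values()))
        elif ld.allele_universe:
            tops.append(max(ld.allele_universe))
    return max(tops) if tops else None


def evaluate_panels(
    table: GenotypeTable,
    error_rates,
    panels: Mapping[str, Sequence[str]],
    convention: str = "unordered",
) -> list:
    """Score each named locus subset on diversity, identity and error axes.

    ``error_rates`` is a list of :class:`~strpanel.error_qc.ErrorRates` or a
    mapping locus -> (ado, fa); undefined ADO entries count as 0 in panel
    means.  Panels are returned ordered from least to most informative
    (descending multilocus P_ID).
    """
    all_loci = sorted({lo for loci in panels.values() for lo in loci})
    unknown = [lo for lo in all_loci if lo not in table.locus_names]
    if unknown:
        raise KeyError(f"panel loci not in table: {unknown}")

    summaries = {s.locus: s for s in summarize_loci(table, all_loci)}
    profile = identity_profile(table, all_loci)
    rates = _rates_map(error_rates)

    out = []
    for name, loci in panels.items():
        loci = list(loci)
        ne = np.array([summaries[lo].Ne for lo in loci])
        ho = np.array([summaries[lo].Ho for lo in loci])
        he = np.array([summaries[lo].He for lo in loci])
        mm = observed_mismatch_distribution(table, loci, convention=convention)
        ado = np.array([(rates.get(lo, (0.0, 0.0))[0] or 0.0) for lo in loci])
        fa = np.array([(rates.get(lo, (0.0, 0.0))[1] or 0.0) for lo in loci])
        n = len(loci)

        def se(x):
            return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

        out.append(
            PanelEvaluation(
                name=name,
                loci=loci,
                ne_mean=float(ne.mean()),
                ho_mean=float(ho.mean()),
                ho_se=se(ho),
                he_mean=float(he.mean()),
                he_se=se(he),
                pid=multilocus_identity(profile.pid, loci),
                pidsib=multilocus_identity(profile.pidsib, loci),
                mm_pairs={m: mm.pairs_at(m) for m in range(4)},
                mean_ado=float(ado.mean()),
                mean_fa=float(fa.mean()),
                max_fragment_bp=_max_fragment(table, loci),
                total_pairs=mm.total_pairs,
                pair_convention=convention,
            )
        )
    out.sort(key=lambda e: -e.pid)
    return out


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionCriteria:
    """Operational form of the three selection criteria.

    ``fa_max`` / ``ado_max`` are hard per-locus error caps (None disables a
    cap); ``pidsib_max`` is the ceiling the selected panel's multilocus
    P_IDsib must stay strictly below; with ``prefer_short_fragments`` loci of
    equal informativeness re-enter shortest first.

    The default FA cap sits between the worst FA rate observed on the ABB
    reference panel's retained loci (Mu15, 0.035) and the rate that got a
    locus dropped from routine use there (REN144A06, 0.039); the default
    P_IDsib ceiling 0.006 corresponds to 0.3 expected genotype collisions
    in a population of 50 — both are declared policy defaults, not
    universal constants, and should be set per study.
    """

    pidsib_max: float = 0.006
    fa_max: "float | None" = 0.037
    ado_max: "float | None" = None
    prefer_short_fragments: bool = True
    required_loci: tuple = ()
    excluded_loci: tuple = ()


@dataclass
class PanelSelection:
    loci: list  # the selected panel, in candidate order
    pidsib: float
    pid: float
    justification: list  # (locus, decision, reason) triples


def select_panel(
    pid_by_locus: Mapping[str, float],
    pidsib_by_locus: Mapping[str, float],
    error_rates,
    criteria: SelectionCriteria = SelectionCriteria(),
    max_fragment_by_locus: "Mapping[str, int] | None" = None,
) -> PanelSelection:
    """Deterministic panel selection under error caps and an identity ceiling.

    Start from every candidate locus; drop loci violating the per-locus
    error caps; if the remaining panel misses ``pidsib_max``, re-admit
    dropped loci in order of informativeness (ascending per-locus P_ID,
    then shorter maximum fragment, then name) until it is met.  Raises
    ``ValueError`` with the best achievable value when no admissible panel
    meets the ceiling.  Output is invariant to input locus order.
    """
    rates = _rates_map(error_rates)
    frag = dict(max_fragment_by_locus or {})
    candidates = sorted(pid_by_locus)
    required = set(criteria.required_loci)
    excluded = set(criteria.excluded_loci) - required
    justification: list = []

    keep, dropped = [], []
    for lo in candidates:
        if lo in excluded:
            justification.append((lo, "excluded", "excluded by configuration"))
            continue
        ado, fa = rates.get(lo, (0.0, 0.0))
        ado = ado or 0.0
        if lo in required:
            keep.append(lo)
            justification.append((lo, "included", "required locus"))
            continue
        if criteria.fa_max is not None and fa > criteria.fa_max:
            dropped.append(lo)
            justification.append(
                (lo, "dropped", f"FA {fa:.3f} exceeds cap {criteria.fa_max:.3f}")
            )
            continue
        if criteria.ado_max is not None and ado > criteria.ado_max:
            dropped.append(lo)
            justification.append(
                (lo, "dropped", f"ADO {ado:.3f} exceeds cap {criteria.ado_max:.3f}")
            )
            continue
        keep.append(lo)
        justification.append((lo, "included", "within error caps"))

    def frag_key(lo):
        return frag.get(lo, 10**9) if criteria.prefer_short_fragments else 0

    readmit_order = sorted(
        dropped, key=lambda lo: (pid_by_locus[lo], frag_key(lo), lo)
    )
    chosen: "tuple | None" = None
    if keep and multilocus_identity(pidsib_by_locus, keep) < criteria.pidsib_max:
        chosen = ()
    else:
        # re-admit the fewest possible error-prone loci; among equal counts
        # take the first admissible combination in informativeness order
        from itertools import combinations as _combos

        for k in range(1, len(readmit_order) + 1):
            for combo in _combos(readmit_order, k):
                if (
                    multilocus_identity(pidsib_by_locus, keep + list(combo))
                    < criteria.pidsib_max
                ):
                    chosen = combo
                    break
            if chosen is not None:
                break
    if chosen is None:
        if not keep + dropped:
            raise ValueError("no admissible locus after applying error caps")
        best = multilocus_identity(pidsib_by_locus, keep + dropped)
        raise ValueError(
            f"P_IDsib ceiling {criteria.pidsib_max} unattainable; best "
            f"achievable {best:.3g}"
        )
    current = keep + list(chosen)
    for lo in chosen:
        justification.append(
            (lo, "re-included", "needed to meet the P_IDsib ceiling")
        )

    selected = [lo for lo in candidates if lo in set(current)]
    return PanelSelection(
        loci=selected,
        pidsib=multilocus_identity(pidsib_by_locus, selected),
        pid=multilocus_identity(pid_by_locus, selected),
        justification=justification,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = [
    "panel", "n_loci", "Ne_mean", "Ho_mean", "Ho_se", "He_mean", "He_se",
    "PID", "PIDsib", "MM0", "MM1", "MM2", "MM3", "mean_ADO", "mean_FA",
    "max_fragment_bp", "total_pairs", "pair_convention", "loci",
]

_LOCUS_COLUMNS = [
    "locus", "A", "Ne", "Ho", "He", "uHe", "I", "HWE_p", "n_typed",
]


def report(
    evaluations: Sequence[PanelEvaluation],
    path,
    locus_summaries: "Sequence[LocusSummary] | None" = None,
) -> None:
    """Write per-panel (and optionally per-locus) TSV reports plus a summary.

    ``path`` is a directory; it receives ``panels.tsv``, ``loci.tsv`` (when
    summaries are given) and ``summary.txt``.  Output is deterministic:
    re-running on the same inputs is byte-identical.
    """
    os.makedirs(path, exist_ok=True)

    lines = ["\t".join(_PANEL_COLUMNS)]
    for e in evaluations:
        lines.append(
            "\t".join(
                [
                    e.name,
                    str(len(e.loci)),
                    f"{e.ne_mean:.3f}",
                    f"{e.ho_mean:.3f}",
                    f"{e.ho_se:.3f}",
                    f"{e.he_mean:.3f}",
                    f"{e.he_se:.3f}",
                    f"{e.pid:.3e}",
                    f"{e.pidsib:.3e}",
                    str(e.mm_pairs.get(0, 0)),
                    str(e.mm_pairs.get(1, 0)),
                    str(e.mm_pairs.get(2, 0)),
                    str(e.mm_pairs.get(3, 0)),
                    f"{e.mean_ado:.3f}",
                    f"{e.mean_fa:.3f}",
                    str(e.max_fragment_bp if e.max_fragment_bp else ""),
                    str(e.total_pairs),
                    e.pair_convention,
                    ",".join(e.loci),
                ]
            )
        )
    with open(os.path.join(path, "panels.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if locus_summaries is not None:
        lines = ["\t".join(_LOCUS_COLUMNS)]
        for s in locus_summaries:
            lines.append(
                "\t".join(
                    [
                        s.locus,
                        str(s.A),
                        f"{s.Ne:.3f}",
                        f"{s.Ho:.3f}",
                        f"{s.He:.3f}",
                        f"{s.uHe:.3f}",
                        f"{s.I:.3f}",
                        f"{s.hwe_p:.4f}",
                        str(s.n_typed),
                    ]
                )
            )
        with open(os.path.join(path, "loci.tsv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")

    with open(os.path.join(path, "summary.txt"), "w") as fh:
        fh.write("Panel comparison (least to most informative)\n")
        fh.write("=" * 44 + "\n")
        for e in evaluations:
            fh.write(
                f"{e.name}: {len(e.loci)} loci, PID={e.pid:.3e}, "
                f"PIDsib={e.pidsib:.3e}, 0MM pairs={e.mm_pairs.get(0, 0)}, "
                f"mean ADO={e.mean_ado:.3f}, mean FA={e.mean_fa:.3f}\n"
            )
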