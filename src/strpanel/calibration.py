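"""Inter-laboratory allele-size calibration.

Different labs score the same STR allele at different absolute fragment
sizes (different primers, dyes, size standards).  For a given locus the
discrepancy is a constant integer offset in bp, so genotypes from lab A can
be converted into lab B's frame by adding a per-locus *calibration key*
inferred from reference samples typed in both labs.

A sex marker (e.g. Amelogenin) amplifies two fragment classes (X and Y) with
different primer geometry, so it carries one offset per fragment class
rather than a single constant; the classes are separated by fragment size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .genotypes import (
    MISSING,
    GenotypeTable,
    MultilocusGenotype,
    canonical,
    count_mismatches,
)


class SplitOffset(NamedTuple):
    """Two-class offset: fragments below ``threshold`` get ``low``, others ``high``."""

    threshold: int
    low: int
    high: int


def shift_call(call, offset):
    """Apply an integer or :class:`SplitOffset` shift to a call's alleles."""
    if call is MISSING:
        return MISSING
    if isinstance(offset, SplitOffset):
        shifted = tuple(
            a + (offset.low if a < offset.threshold else offset.high) for a in call
        )
    else:
        shifted = tuple(a + int(offset) for a in call)
    if any(a <= 0 for a in shifted):
        raise ValueError(f"offset {offset} drives allele size non-positive: {call}")
    return canonical(shifted)


@dataclass
class CalibrationKey:
    """Per-locus conversion key between two lab size frames.

    ``offset`` is a signed integer (add to frame-A scores to obtain frame-B
    scores), or a :class:`SplitOffset` for dual-class loci such as a sex
    marker.  ``consistent`` is False when the shared samples do not agree on
    a single (or single-per-class) integer offset; ``conflicts`` then lists
    the offending (sample_id, call_A, call_B) triples.
    """

    locus: str
    offset: "int | SplitOffset | None"
    support: int = 0
    consistent: bool = True
    conflicts: list = field(default_factory=list)


def _pairs_for_locus(shared, locus):
    """Rank-aligned (sizeA, sizeB) pairs plus conflict records for a locus."""
    pairs = []  # (sample_id, a, b)
    conflicts = []
    for ga, gb in shared:
        ca, cb = ga.call(locus), gb.call(locus)
        if ca is MISSING or cb is MISSING:
            continue
        if len(ca) != len(cb):
            conflicts.append((ga.sample_id, ca, cb))
            continue
        # offsets are monotone shifts, so rank pairing is order-preserving
        for a, b in zip(ca, cb):
            pairs.append((ga.sample_id, a, b))
    return pairs, conflicts


def infer_key(shared, locus: str, dual: bool = False) -> CalibrationKey:
    """Infer the calibration key for one locus from shared reference samples.

    ``shared`` is a sequence of (genotype_in_frame_A, genotype_in_frame_B)
    pairs for the same physical individuals.  With ``dual`` set (sex marker),
    fragments are partitioned into two size classes and one offset is fitted
    per class; the classes must be separable by fragment size.
    """
    pairs, conflicts = _pairs_for_locus(shared, locus)
    if not pairs:
        return CalibrationKey(locus=locus, offset=None, support=0, consistent=False)

    offsets = sorted({b - a for _, a, b in pairs})
    if not dual:
        if len(offsets) == 1 and conflicts == []:
            return CalibrationKey(
                locus=locus, offset=offsets[0], support=len(pairs)
            )
        bad = conflicts + [
            (sid, a, b) for sid, a, b in pairs if b - a != offsets[0]
        ]
        return CalibrationKey(
            locus=locus, offset=None, support=len(pairs),
            consistent=False, conflicts=bad,
        )

    # dual-class fit: group pairs by offset; two groups whose frame-A size
    # ranges do not overlap define the class boundary
    by_off: dict = {}
    for sid, a, b in pairs:
        by_off.setdefault(b - a, []).append((sid, a, b))
    if len(by_off) == 1 and not conflicts:
        off = next(iter(by_off))
        return CalibrationKey(
            locus=locus,
            offset=SplitOffset(threshold=0, low=off, high=off),
            support=len(pairs),
        )
    if len(by_off) == 2 and not conflicts:
        (o1, p1), (o2, p2) = sorted(
            by_off.items(), key=lambda kv: max(a for _, a, _b in kv[1])
        )
        max1 = max(a for _, a, _b in p1)
        min2 = min(a for _, a, _b in p2)
        if max1 < min2:  # separable classes
            return CalibrationKey(
                locus=locus,
                offset=SplitOffset(threshold=(max1 + min2 + 1) // 2, low=o1, high=o2),
                support=len(pairs),
            )
    return CalibrationKey(
        locus=locus, offset=None, support=len(pairs),
        consistent=False, conflicts=conflicts + pairs,
    )


def infer_keys(shared, loci=None, dual_loci: Sequence[str] = ()) -> list:
    """Infer calibration keys for every locus typed in the shared samples.

    ``shared``: (frame-A genotype, frame-B genotype) pairs.  ``dual_loci``
    names loci fitted with two per-class offsets (sex markers).
    """
    if loci is None:
        names: list = []
        for ga, _ in shared:
            for n in ga.calls:
                if n not in names:
                    names.append(n)
        loci = names
    return [infer_key(shared, locus, dual=locus in dual_loci) for locus in loci]


def convert(table: GenotypeTable, keys) -> GenotypeTable:
    """Convert every call in ``table`` into the keys' target frame.

    Every analyzed locus present in the table must have a consistent key;
    MISSING calls are preserved.
    """
    key_by_locus = {k.locus: k for k in keys}
    for name in table.locus_names:
        k = key_by_locus.get(name)
        if k is None:
            raise KeyError(f"no calibration key for locus {name!r}")
        if not k.consistent or k.offset is None:
            raise ValueError(f"calibration key for locus {name!r} is inconsistent")
    individuals = []
    for g in table.individuals:
        calls = {
            name: shift_call(c, key_by_locus[name].offset)
            for name, c in g.calls.items()
        }
        individuals.append(
            MultilocusGenotype(
                sample_id=g.sample_id,
                individual_id=g.individual_id,
                calls=calls,
                sex=g.sex,
                source=g.source,
            )
        )
    return GenotypeTable(loci=list(table.loci), individuals=individuals,
                         groups=dict(table.groups))


def negate_keys(keys) -> list:
    """Keys for the inverse conversion (frame B back to frame A)."""
    out = []
    for k in keys:
        if k.offset is None:
            out.append(k)
        elif isinstance(k.offset, SplitOffset):
            off = SplitOffset(
                threshold=k.offset.threshold + k.offset.low,
                low=-k.offset.low,
                high=-k.offset.high,
            )
            out.append(CalibrationKey(k.locus, off, k.support, k.consistent))
        else:
            out.append(CalibrationKey(k.locus, -k.offset, k.support, k.consistent))
    return out


@dataclass
class CrossMatch:
    """One A-individual's match candidates in database B after conversion."""

    sample_id: str
    perfect: list = field(default_factory=list)  # B sample_ids, 0 mismatches
    partial: list = field(default_factory=list)  # (B sample_id, n_mm, [loci])


@dataclass
class CrossMatchReport:
    matches: list  # CrossMatch per A individual with >=1 candidate
    unmatched: list  # A sample_ids with no candidate within max_mismatch
    n_pairs_compared: int = 0


def crossmatch(
    dbA: GenotypeTable,
    dbB: GenotypeTable,
    keys,
    max_mismatch: int = 0,
    loci: Sequence[str] | None = None,
) -> CrossMatchReport:
    """Match individuals across two lab databases after frame conversion.

    ``dbA`` is converted into B's frame with ``keys``; every A-individual is
    compared against every B-individual over ``loci`` (default: loci common
    to both tables).  B-individuals within ``max_mismatch`` mismatching loci
    are listed, with the mismatching loci named.
    """
    a_conv = convert(dbA, [k for k in keys if k.locus in dbA.locus_names])
    if loci is None:
        loci = [n for n in a_conv.locus_names if n in dbB.locus_names]
    matches, unmatched = [], []
    n_pairs = 0
    for ga in a_conv.individuals:
        rec = CrossMatch(sample_id=ga.sample_id)
        for gb in dbB.individuals:
            n_pairs += 1
            mm, comp, _miss = count_mismatches(ga, gb, loci)
            if comp == 0 or mm > max_mismatch:
                continue
            if mm == 0:
                rec.perfect.append(gb.sample_id)
            else:
                bad = [
                    lo
                    for lo in loci
                    if ga.call(lo) is not MISSING
                    and gb.call(lo) is not MISSING
                    and ga.call(lo) != gb.call(lo)
                ]
                rec.partial.append((gb.sample_id, mm, bad))
        if rec.perfect or rec.partial:
            matches.append(rec)
        else:
            unmatched.append(ga.sample_id)
    return CrossMatchReport(matches=matches, unmatched=unmatched,
                            n_pairs_compared=n_pairs)
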