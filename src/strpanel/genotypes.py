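"""Core data model and I/O for codominant STR genotype data.

Alleles are integer fragment sizes in base pairs, as scored on a capillary
sequencer after binning.  A diploid genotype call is an unordered pair of
sizes stored in canonical (ascending) order; a homozygote repeats the same
size twice.  Missing data is an explicit :data:`MISSING` sentinel, never the
``0`` used on disk by the GenAlEx codominant layout.

Replicate-level data (one row per independent PCR of the same extract) may
record more than two alleles at a locus; those multisets are preserved as-is
because "more than 2 alleles in one amplification" is the operational
signature of a mixed sample.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence


class _Missing:
    """Singleton sentinel for a failed / absent genotype call."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: A genotype call: a sorted tuple of integer fragment sizes, or MISSING.
#: Diploid calls have length 2; sex-marker calls may have length 1 or 2;
#: replicate-level multisets may be longer (mixture candidates).
Call = "tuple[int, ...] | _Missing"


def canonical(alleles: Iterable[int]) -> tuple[int, ...]:
    """Return the canonical (sorted ascending) form of an allele multiset."""
    out = tuple(sorted(int(a) for a in alleles))
    if any(a <= 0 for a in out):
        raise ValueError(f"allele sizes must be positive integers, got {out}")
    return out


class Origin(str, Enum):
    URSID = "ursid"
    CANID = "canid"
    SEX_MARKER = "sex_marker"


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class Source(str, Enum):
    BLOOD = "blood"
    TISSUE = "tissue"
    HAIR = "hair"
    FECES = "feces"


@dataclass(frozen=True)
class LocusDefinition:
    """An STR locus: its allele universe and per-laboratory size ranges.

    ``size_range_by_lab`` maps a lab identifier to the (min, max) fragment
    sizes that lab reports for this locus; different labs may score the same
    allele at different absolute sizes (see :mod:`strpanel.calibration`).
    """

    name: str
    allele_universe: frozenset[int] = frozenset()
    size_range_by_lab: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    origin: Origin = Origin.URSID
    multiplex_group: int = 1

    def __post_init__(self):
        if any(a <= 0 for a in self.allele_universe):
            raise ValueError(f"{self.name}: allele sizes must be positive")

    def contains(self, allele: int, lab: str | None = None) -> bool:
        """Whether ``allele`` is inside the known universe (or a lab's range)."""
        if lab is not None and lab in self.size_range_by_lab:
            lo, hi = self.size_range_by_lab[lab]
            return lo <= allele <= hi
        return allele in self.allele_universe


@dataclass
class MultilocusGenotype:
    """One individual's unordered diploid calls across loci."""

    sample_id: str
    calls: dict
    individual_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    source: Source | None = None

    def call(self, locus: str):
        return self.calls.get(locus, MISSING)

    def is_missing(self, locus: str) -> bool:
        return self.calls.get(locus, MISSING) is MISSING


@dataclass
class GenotypeTable:
    """A panel of loci and the individuals genotyped on it.

    ``groups`` optionally labels a subset of individuals (e.g. two sampling
    periods) for grouped statistics such as F-statistics or private alleles.
    """

    loci: list[LocusDefinition]
    individuals: list[MultilocusGenotype]
    groups: dict = field(default_factory=dict)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def autosomal_loci(self) -> list[LocusDefinition]:
        return [l for l in self.loci if l.origin is not Origin.SEX_MARKER]

    def locus(self, name: str) -> LocusDefinition:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not in table")

    def subset_loci(self, names: Sequence[str]) -> "GenotypeTable":
        keep = [l for l in self.loci if l.name in set(names)]
        kept = {l.name for l in keep}
        inds = [
            MultilocusGenotype(
                sample_id=g.sample_id,
                individual_id=g.individual_id,
                calls={n: c for n, c in g.calls.items() if n in kept},
                sex=g.sex,
                source=g.source,
            )
            for g in self.individuals
        ]
        return GenotypeTable(loci=keep, individuals=inds, groups=dict(self.groups))

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        keep = set(ids)
        inds = [g for g in self.individuals if g.sample_id in keep]
        groups = {k: v for k, v in self.groups.items() if k in keep}
        return GenotypeTable(loci=list(self.loci), individuals=inds, groups=groups)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.locus_names == other.locus_names
            and self.groups == other.groups
            and [(g.sample_id, g.sex, dict(g.calls)) for g in self.individuals]
            == [(g.sample_id, g.sex, dict(g.calls)) for g in other.individuals]
        )


@dataclass
class ReplicateSet:
    """Independent PCR replicates of one sample (the multiple-tubes input)."""

    sample_id: str
    replicates: list  # list of dict locus -> Call (allele multisets allowed)
    lab: str | None = None

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ValueError("a ReplicateSet needs at least one replicate")

    def positive_calls(self, locus: str) -> list:
        """Non-missing calls at ``locus`` across replicates."""
        return [
            r[locus]
            for r in self.replicates
            if r.get(locus, MISSING) is not MISSING
        ]


@dataclass
class AlleleFrequencies:
    """Per-locus allele relative frequencies over 2N typed gene copies."""

    locus: str
    freqs: dict
    n_typed: int

    def __post_init__(self):
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.locus}: frequencies sum to {total}, not 1")

    @property
    def alleles(self) -> list[int]:
        return sorted(self.freqs)

    def vector(self):
        import numpy as np

        return np.array([self.freqs[a] for a in self.alleles])


class FormatError(ValueError):
    """Raised when an on-disk genotype file violates its declared layout."""


class EstimationError(ValueError):
    """Raised when a statistic is undefined for the data at hand."""


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV
# ---------------------------------------------------------------------------
# Layout (two header rows, then one row per sample):
#   row 1: n_loci, n_samples, n_groups, size_g1, size_g2, ...
#   row 2: Sample, Pop, <locus1>, "", <locus2>, "", ...[, Sex, <sexmarker>]
#   data : sample_id, group, a1, a2, b1, b2, ...[, F/M/U, "158;212"]
# 0 encodes missing on disk; internally missing is the MISSING sentinel.
# A sex-marker locus is excluded from the codominant two-column block and
# carried in a trailing side column as a semicolon-joined fragment list.

_SEX_CODE = {Sex.F: "F", Sex.M: "M", Sex.UNKNOWN: "U"}
_CODE_SEX = {v: k for k, v in _SEX_CODE.items()}


def read_genalex(path) -> GenotypeTable:
    """Read a GenAlEx-style codominant CSV into a :class:`GenotypeTable`.

    ``0 0`` cells become MISSING; calls are canonicalized (sorted ascending).
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise FormatError(f"{path}: expected two header rows")
    counts, titles = rows[0], rows[1]
    try:
        n_loci = int(counts[0])
        n_samples = int(counts[1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed counts header: {counts!r}") from exc

    expected_min = 2 + 2 * n_loci
    if len(titles) < expected_min:
        raise FormatError(
            f"{path}: header declares {n_loci} loci (needs {expected_min} title "
            f"columns) but title row has {len(titles)}"
        )
    locus_names = []
    for i in range(n_loci):
        name = titles[2 + 2 * i].strip()
        pair = titles[2 + 2 * i + 1].strip()
        if not name:
            raise FormatError(f"{path}: empty locus name at column {2 + 2 * i}")
        if pair:
            raise FormatError(
                f"{path}: locus {name!r} must span two columns (second column "
                f"title must be blank, got {pair!r})"
            )
        locus_names.append(name)

    extra = [t.strip() for t in titles[expected_min:] if t.strip()]
    has_sex = "Sex" in extra
    sex_marker_name = None
    if has_sex:
        trailing = [t for t in extra if t != "Sex"]
        if trailing:
            sex_marker_name = trailing[0]

    data_rows = [r for r in rows[2:] if any(c.strip() for c in r)]
    if len(data_rows) != n_samples:
        raise FormatError(
            f"{path}: header declares {n_samples} samples but found {len(data_rows)}"
        )

    loci = [LocusDefinition(name=n) for n in locus_names]
    if sex_marker_name:
        loci.append(LocusDefinition(name=sex_marker_name, origin=Origin.SEX_MARKER))

    individuals: list[MultilocusGenotype] = []
    groups: dict = {}
    group_labels_seen = []
    for r in data_rows:
        if len(r) < expected_min:
            raise FormatError(f"{path}: short data row: {r!r}")
        sample_id = r[0].strip()
        group = r[1].strip()
        calls: dict = {}
        for i, name in enumerate(locus_names):
            raw = (r[2 + 2 * i].strip(), r[2 + 2 * i + 1].strip())
            try:
                a, b = int(raw[0] or 0), int(raw[1] or 0)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer allele {raw!r} for {name} / {sample_id}"
                ) from exc
            calls[name] = MISSING if (a == 0 or b == 0) else canonical((a, b))
        sex = Sex.UNKNOWN
        if has_sex:
            tail = r[expected_min:]
            sex = _CODE_SEX.get(tail[0].strip() if tail else "U", Sex.UNKNOWN)
            if sex_marker_name:
                frag = tail[1].strip() if len(tail) > 1 else ""
                calls[sex_marker_name] = (
                    canonical(frag.split(";")) if frag else MISSING
                )
        individuals.append(
            MultilocusGenotype(sample_id=sample_id, calls=calls, sex=sex)
        )
        if group:
            groups[sample_id] = group
            if group not in group_labels_seen:
                group_labels_seen.append(group)

    # the table carries groups only when more than one label is present
    if len(group_labels_seen) <= 1:
        groups = {}
    return GenotypeTable(loci=loci, individuals=individuals, groups=groups)


def write_genalex(table: GenotypeTable, path) -> None:
    """Write ``table`` as GenAlEx codominant CSV (0 = missing); byte-stable."""
    auto = [l.name for l in table.autosomal_loci]
    sex_loci = [l.name for l in table.loci if l.origin is Origin.SEX_MARKER]
    sex_marker = sex_loci[0] if sex_loci else None

    labels = []
    for g in table.individuals:
        lab = table.groups.get(g.sample_id, "pop1")
        if lab not in labels:
            labels.append(lab)
    if not labels:
        labels = ["pop1"]
    sizes = {
        lab: sum(
            1 for g in table.individuals if table.groups.get(g.sample_id, "pop1") == lab
        )
        for lab in labels
    }

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(
        [len(auto), len(table.individuals), len(labels)] + [sizes[l] for l in labels]
    )
    title = ["Sample", "Pop"]
    for name in auto:
        title += [name, ""]
    title.append("Sex")
    if sex_marker:
        title.append(sex_marker)
    w.writerow(title)
    for g in table.individuals:
        row = [g.sample_id, table.groups.get(g.sample_id, "pop1")]
        for name in auto:
            c = g.call(name)
            row += ["0", "0"] if c is MISSING else [str(c[0]), str(c[1])]
        row.append(_SEX_CODE[g.sex])
        if sex_marker:
            c = g.call(sex_marker)
            row.append("" if c is MISSING else ";".join(str(a) for a in c))
        w.writerow(row)
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Replicate-level long TSV
# ---------------------------------------------------------------------------

_REPL_COLUMNS = ["sample_id", "replicate", "locus", "alleles", "lab"]


def read_replicates(path) -> list[ReplicateSet]:
    """Read a long-format replicate TSV into :class:`ReplicateSet` objects.

    Columns: sample_id, replicate, locus, alleles (semicolon-joined, empty =
    missing), lab.  Allele multisets with 3+ entries are preserved — they are
    mixed-sample candidates, not errors.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _REPL_COLUMNS:
            raise FormatError(
                f"{path}: expected columns {_REPL_COLUMNS}, got {reader.fieldnames}"
            )
        rows = list(reader)

    seen = set()
    per_sample: dict = {}
    labs: dict = {}
    for row in rows:
        key = (row["sample_id"], row["replicate"], row["locus"])
        if key in seen:
            raise FormatError(f"{path}: duplicate row for {key}")
        seen.add(key)
        sid = row["sample_id"]
        idx = int(row["replicate"])
        alleles = row["alleles"].strip()
        call = canonical(alleles.split(";")) if alleles else MISSING
        per_sample.setdefault(sid, {}).setdefault(idx, {})[row["locus"]] = call
        labs.setdefault(sid, row.get("lab") or None)

    out = []
    for sid, by_idx in per_sample.items():
        reps = [by_idx[i] for i in sorted(by_idx)]
        out.append(ReplicateSet(sample_id=sid, replicates=reps, lab=labs.get(sid)))
    return out


def write_replicates(rsets: Sequence[ReplicateSet], path) -> None:
    """Inverse of :func:`read_replicates`; MISSING becomes an empty field."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REPL_COLUMNS)
        for rs in rsets:
            for i, rep in enumerate(rs.replicates, start=1):
                for locus in sorted(rep):
                    call = rep[locus]
                    txt = "" if call is MISSING else ";".join(map(str, call))
                    w.writerow([rs.sample_id, i, locus, txt, rs.lab or ""])


# ---------------------------------------------------------------------------
# Statistics primitives
# ---------------------------------------------------------------------------


def allele_frequencies(
    table: GenotypeTable, locus: str, group: str | None = None
) -> AlleleFrequencies:
    """Allele relative frequencies at ``locus`` over non-missing calls.

    With ``group`` given, only individuals carrying that group label count.
    """
    if locus not in table.locus_names:
        raise KeyError(f"locus {locus!r} not in table")
    counts: dict = {}
    n_typed = 0
    for g in table.individuals:
        if group is not None and table.groups.get(g.sample_id) != group:
            continue
        c = g.call(locus)
        if c is MISSING:
            continue
        n_typed += 1
        for a in c:
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise EstimationError(f"{locus}: no non-missing calls in scope")
    return AlleleFrequencies(
        locus=locus,
        freqs={a: n / total for a, n in sorted(counts.items())},
        n_typed=n_typed,
    )


def count_mismatches(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    loci: Sequence[str],
    strict_missing: bool = False,
) -> tuple[int, int, int]:
    """Compare two genotypes over ``loci``.

    Returns ``(n_mismatch, n_compared, n_missing)``.  A locus mismatches iff
    both calls are non-missing and the unordered pairs differ.  Loci where
    either call is MISSING are excluded from comparison (pairwise deletion)
    and counted separately — unless ``strict_missing`` is set, in which case
    a MISSING-vs-called locus counts as a mismatch.
    """
    if not loci:
        raise ValueError("empty locus list")
    mism = comp = miss = 0
    for locus in loci:
        c1, c2 = g1.call(locus), g2.call(locus)
        if c1 is MISSING or c2 is MISSING:
            if strict_missing and (c1 is MISSING) != (c2 is MISSING):
                mism += 1
                comp += 1
            else:
                miss += 1
            continue
        comp += 1
        if c1 != c2:
            mism += 1
    return mism, comp, miss
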