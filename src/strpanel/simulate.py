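"""Synthetic genotype data with the statistical structure the analyses assume.

The generator produces Hardy–Weinberg populations (optionally salted with
full-sib pairs), replicate PCR amplifications with allelic dropout (ADO),
false alleles (FA) and amplification failure, two-genotype mixtures, and
two-laboratory allele-size frames — everything needed to exercise diversity,
identity, error-rate and calibration analyses end to end.

Error model per replicate and locus (single shared convention, also used by
the reliability calculation in :mod:`strpanel.error_qc`):

1. with probability ``missing_rate`` the amplification fails (MISSING);
2. else, if the true genotype is heterozygous, with probability ``ado`` one
   allele (chosen uniformly) drops out, yielding a false homozygote;
3. independently, with probability ``fa`` one of the two allele copies
   (chosen uniformly) is *replaced* by an artifact allele drawn uniformly
   from the locus universe excluding the alleles already in the call (a
   false allele is by definition one the call does not carry; on a locus
   whose universe offers no spare allele the event is unrealizable).

FA replaces rather than adds, so a single-source replicate never shows more
than two alleles; three or more alleles in one amplification is therefore
the unambiguous mixture signature, as it is in real multiple-tubes data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .calibration import SplitOffset, shift_call
from .genotypes import (
    MISSING,
    GenotypeTable,
    LocusDefinition,
    MultilocusGenotype,
    Origin,
    ReplicateSet,
    Sex,
    canonical,
)


# ---------------------------------------------------------------------------
# Frequencies with a prescribed expected heterozygosity
# ---------------------------------------------------------------------------


def frequencies_for_heterozygosity(n_alleles: int, target_he: float) -> np.ndarray:
    """Allele frequency vector with He = 1 - sum(p^2) equal to ``target_he``.

    For two alleles the solution is the closed-form root of 2pq = He.  For
    more alleles a one-parameter family is used — one major allele with
    frequency p, the remaining mass split equally — and p is solved
    numerically.  Frequencies are returned in descending order.
    """
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    he_max = (n_alleles - 1) / n_alleles
    if not 0.0 < target_he <= he_max or not np.isfinite(target_he):
        raise ValueError(
            f"target He {target_he} unreachable with {n_alleles} alleles: "
            f"must lie in (0, {he_max:.6g}] (the uniform-frequency maximum)"
        )
    if n_alleles == 2:
        p = (1.0 + np.sqrt(1.0 - 2.0 * target_he)) / 2.0
        vec = np.array([p, 1.0 - p])
    else:
        k = n_alleles - 1

        def he(p):
            return 1.0 - p * p - (1.0 - p) ** 2 / k

        p = brentq(lambda x: he(x) - target_he, 1.0 / n_alleles, 1.0 - 1e-12,
                   xtol=1e-13)
        vec = np.array([p] + [(1.0 - p) / k] * k)
    assert abs((1.0 - np.sum(vec**2)) - target_he) < 1e-9
    return vec


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimLocus:
    """One simulated locus: allele sizes, frequencies, error rates, frames."""

    name: str
    alleles: tuple  # integer sizes, target (e.g. Lab3) frame
    frequencies: tuple  # same order as alleles
    ado: float = 0.0
    fa: float = 0.0
    origin: Origin = Origin.URSID
    multiplex_group: int = 1
    range_by_lab: Mapping[str, tuple] = field(default_factory=dict)
    offset: "int | None" = None  # add to Lab2 scores to obtain target frame

    def __post_init__(self):
        if not 0.0 <= self.ado <= 1.0 or not 0.0 <= self.fa <= 1.0:
            raise ValueError(f"{self.name}: rates must lie in [0, 1]")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: frequencies must sum to 1")
        if len(self.alleles) != len(self.frequencies):
            raise ValueError(f"{self.name}: alleles/frequencies length mismatch")

    def definition(self) -> LocusDefinition:
        return LocusDefinition(
            name=self.name,
            allele_universe=frozenset(self.alleles),
            size_range_by_lab=dict(self.range_by_lab),
            origin=self.origin,
            multiplex_group=self.multiplex_group,
        )


@dataclass(frozen=True)
class SexMarker:
    name: str = "AMG"
    x_size: int = 158
    y_size: int = 212
    range_by_lab: Mapping[str, tuple] = field(default_factory=dict)
    offsets: tuple = (0, 0)  # (X-fragment, Y-fragment) Lab2 -> target frame


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate a study-like dataset deterministically."""

    loci: tuple
    n_individuals: int = 113
    sib_family_fraction: float = 0.2
    n_replicates: int = 4
    missing_rate: float = 0.05
    sex_marker: "SexMarker | None" = None
    panels: Mapping[str, tuple] = field(default_factory=dict)
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        for r in (self.sib_family_fraction, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates/fractions must lie in [0, 1]")
        if self.n_individuals < 1 or self.n_replicates < 1:
            raise ValueError("n_individuals and n_replicates must be positive")

    @property
    def locus_names(self) -> list:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> SimLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def lab_offsets(self) -> dict:
        """Per-locus offsets mapping the alternate (Lab2) frame to this one.

        SplitOffset thresholds are expressed in the Lab2 frame (the frame the
        offsets apply to).  Loci without a Lab2 range (never scored there)
        are omitted.
        """
        out = {}
        for l in self.loci:
            if l.offset is not None:
                out[l.name] = l.offset
        if self.sex_marker is not None:
            sm = self.sex_marker
            out[sm.name] = SplitOffset(
                threshold=(sm.x_size + sm.y_size) // 2 - sm.offsets[0],
                low=sm.offsets[0],
                high=sm.offsets[1],
            )
        return out

    @property
    def offsets_to_lab2(self) -> dict:
        """Per-locus offsets taking this (target-frame) table into Lab2 scores.

        The inverse of :attr:`lab_offsets`; SplitOffset thresholds here are in
        the target frame.
        """
        out = {}
        for l in self.loci:
            if l.offset is not None:
                out[l.name] = -l.offset
        if self.sex_marker is not None:
            sm = self.sex_marker
            out[sm.name] = SplitOffset(
                threshold=(sm.x_size + sm.y_size) // 2,
                low=-sm.offsets[0],
                high=-sm.offsets[1],
            )
        return out

    def ado_by_locus(self) -> dict:
        return {l.name: l.ado for l in self.loci}

    def fa_by_locus(self) -> dict:
        return {l.name: l.fa for l in self.loci}

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def locus_definitions(self) -> list:
        defs = [l.definition() for l in self.loci]
        if self.sex_marker is not None:
            sm = self.sex_marker
            defs.append(
                LocusDefinition(
                    name=sm.name,
                    allele_universe=frozenset({sm.x_size, sm.y_size}),
                    size_range_by_lab=dict(sm.range_by_lab),
                    origin=Origin.SEX_MARKER,
                )
            )
        return defs


def _spread_sizes(lo: int, hi: int, n: int) -> tuple:
    """n distinct integer sizes evenly spread over [lo, hi]."""
    if n == 1:
        return (lo,)
    sizes = sorted({round(lo + k * (hi - lo) / (n - 1)) for k in range(n)})
    if len(sizes) != n:
        raise ValueError(f"range [{lo},{hi}] too narrow for {n} distinct sizes")
    return tuple(sizes)


def load_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a structured YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> SimulationConfig:
    loci = []
    for entry in doc["loci"]:
        lo3, hi3 = entry["range_lab3"]
        alleles = tuple(entry.get("alleles")
                        or _spread_sizes(lo3, hi3, entry["n_alleles"]))
        freqs = entry.get("frequencies")
        if freqs is None:
            freqs = tuple(
                frequencies_for_heterozygosity(len(alleles), entry["he"])
            )
        ranges = {"Lab3": (lo3, hi3)}
        if entry.get("range_lab2"):
            ranges["Lab2"] = tuple(entry["range_lab2"])
        loci.append(
            SimLocus(
                name=entry["name"],
                alleles=alleles,
                frequencies=tuple(freqs),
                ado=float(entry.get("ado", 0.0)),
                fa=float(entry.get("fa", 0.0)),
                origin=Origin(entry.get("origin", "ursid")),
                multiplex_group=int(entry.get("multiplex", 1)),
                range_by_lab=ranges,
                offset=entry.get("offset"),
            )
        )
    sm = None
    if "sex_marker" in doc and doc["sex_marker"]:
        d = doc["sex_marker"]
        sm = SexMarker(
            name=d.get("name", "AMG"),
            x_size=int(d["x_size"]),
            y_size=int(d["y_size"]),
            range_by_lab={
                "Lab2": tuple(d["range_lab2"]),
                "Lab3": tuple(d["range_lab3"]),
            },
            offsets=tuple(d.get("offsets", (0, 0))),
        )
    return SimulationConfig(
        loci=tuple(loci),
        n_individuals=int(doc.get("n_individuals", 113)),
        sib_family_fraction=float(doc.get("sib_family_fraction", 0.2)),
        n_replicates=int(doc.get("n_replicates", 4)),
        missing_rate=float(doc.get("missing_rate", 0.0)),
        sex_marker=sm,
        panels={k: tuple(v) for k, v in doc.get("panels", {}).items()},
        seed=int(doc.get("seed", 0)),
        name=doc.get("name", "custom"),
    )


def abb_like_config(seed: "int | None" = None) -> SimulationConfig:
    """The packaged profile emulating the Apennine brown bear study population."""
    ref = importlib.resources.files("strpanel").joinpath("data/abb_like.yaml")
    doc = yaml.safe_load(ref.read_text())
    cfg = config_from_dict(doc)
    return cfg if seed is None else cfg.with_seed(seed)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def rng_for_sample(config: SimulationConfig, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample substream so subsetting is reproducible."""
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(sample_id.encode())])
    )


def _draw_genotype(locus: SimLocus, rng) -> tuple:
    a = rng.choice(len(locus.alleles), size=2, p=np.asarray(locus.frequencies))
    return canonical((locus.alleles[a[0]], locus.alleles[a[1]]))


def sample_population(
    config: SimulationConfig, rng: "np.random.Generator | None" = None
) -> GenotypeTable:
    """Draw a population of unrelated HWE individuals plus full-sib pairs.

    A ``sib_family_fraction`` of the individuals is generated as full-sib
    pairs by Mendelian segregation from two simulated (unsampled) parents;
    the rest are unrelated, each locus drawn independently under HWE.  Sib
    individuals are identifiable by their ``SIB<k>a`` / ``SIB<k>b`` sample
    ids.  Deterministic for a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_sib_pairs = int(round(config.sib_family_fraction * n / 2.0))
    n_unrelated = n - 2 * n_sib_pairs

    individuals = []

    def finish(sample_id: str, calls: dict) -> MultilocusGenotype:
        sex = Sex.UNKNOWN
        if config.sex_marker is not None:
            sm = config.sex_marker
            if rng.random() < 0.5:
                sex = Sex.F
                calls[sm.name] = canonical((sm.x_size, sm.x_size))
            else:
                sex = Sex.M
                calls[sm.name] = canonical((sm.x_size, sm.y_size))
        return MultilocusGenotype(sample_id=sample_id, calls=calls, sex=sex)

    for i in range(n_unrelated):
        calls = {l.name: _draw_genotype(l, rng) for l in config.loci}
        individuals.append(finish(f"UNR{i + 1:04d}", calls))

    for k in range(n_sib_pairs):
        parents = [
            {l.name: _draw_genotype(l, rng) for l in config.loci} for _ in range(2)
        ]
        for tag in ("a", "b"):
            calls = {}
            for l in config.loci:
                ma = parents[0][l.name][rng.integers(2)]
                pa = parents[1][l.name][rng.integers(2)]
                calls[l.name] = canonical((ma, pa))
            individuals.append(finish(f"SIB{k + 1:04d}{tag}", calls))

    return GenotypeTable(loci=config.locus_definitions(), individuals=individuals)


# ---------------------------------------------------------------------------
# Replicate amplification with errors
# ---------------------------------------------------------------------------


def _amplify_call(truth: tuple, locus: SimLocus, config: SimulationConfig, rng):
    if rng.random() < config.missing_rate:
        return MISSING
    call = list(truth)
    if call[0] != call[1] and rng.random() < locus.ado:
        kept = call[rng.integers(2)]
        call = [kept, kept]
    if rng.random() < locus.fa:
        # a false allele is an artifact allele not present in the call; on a
        # locus whose universe offers no such allele the event is unrealizable
        pos = int(rng.integers(2))
        others = [a for a in locus.alleles if a not in call]
        if others:
            call[pos] = others[rng.integers(len(others))]
    return canonical(call)


def amplify_replicates(
    truth: MultilocusGenotype,
    config: SimulationConfig,
    rng: "np.random.Generator | None" = None,
    n_replicates: "int | None" = None,
    loci: "Sequence[str] | None" = None,
) -> ReplicateSet:
    """Simulate independent PCR replicates of one individual's extract.

    The truth genotype must have no MISSING call at the simulated loci.
    Deterministic per sample under the config seed when ``rng`` is omitted.
    """
    if rng is None:
        rng = rng_for_sample(config, truth.sample_id)
    if n_replicates is None:
        n_replicates = config.n_replicates
    names = list(loci) if loci is not None else config.locus_names
    sim_loci = [config.locus(n) for n in names]
    for l in sim_loci:
        if truth.call(l.name) is MISSING:
            raise ValueError(f"truth genotype missing at simulated locus {l.name}")
    reps = []
    for _ in range(n_replicates):
        rep = {
            l.name: _amplify_call(truth.call(l.name), l, config, rng)
            for l in sim_loci
        }
        if config.sex_marker is not None and truth.call(config.sex_marker.name):
            rep[config.sex_marker.name] = truth.call(config.sex_marker.name)
        reps.append(rep)
    return ReplicateSet(sample_id=truth.sample_id, replicates=reps)


def replicate_call_distribution(
    truth: tuple, ado: float, fa: float, universe: Sequence[int]
) -> dict:
    """Exact distribution of a *positive* replicate call given the truth.

    Mirrors the generative error model step for step (ADO on heterozygotes,
    then single-allele FA replacement), conditioning on the amplification
    not failing.  Used as the likelihood in reliability calculations and as
    the analytic oracle for the Monte-Carlo generator.
    """
    universe = sorted(set(int(u) for u in universe))
    a, b = truth
    post_ado = {}
    if a != b:
        post_ado[canonical((a, b))] = 1.0 - ado
        post_ado[canonical((a, a))] = ado / 2.0
        post_ado[canonical((b, b))] = ado / 2.0
    else:
        post_ado[canonical((a, a))] = 1.0
    out: dict = {}
    for call, p in post_ado.items():
        if p == 0.0:
            continue
        out[call] = out.get(call, 0.0) + p * (1.0 - fa)
        if fa > 0.0:
            others = [u for u in universe if u not in call]
            if not others:
                out[call] = out.get(call, 0.0) + p * fa
                continue
            for pos in range(2):
                for u in others:
                    alt = list(call)
                    alt[pos] = u
                    alt_c = canonical(alt)
                    out[alt_c] = out.get(alt_c, 0.0) + p * fa / (2.0 * len(others))
    total = sum(out.values())
    assert abs(total - 1.0) < 1e-9
    return out


# ---------------------------------------------------------------------------
# Mixtures and lab frames
# ---------------------------------------------------------------------------


def make_mixture(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    n_replicates: int = 4,
    loci: "Sequence[str] | None" = None,
) -> ReplicateSet:
    """Replicates of a two-source mixed sample: the union of both genotypes.

    Wherever the allele union exceeds two, replicates show 3+ alleles — the
    mixture signature that QC flags.
    """
    if loci is None:
        loci = sorted(set(g1.calls) | set(g2.calls))
    rep = {}
    for locus in loci:
        c1, c2 = g1.call(locus), g2.call(locus)
        union = set(() if c1 is MISSING else c1) | set(() if c2 is MISSING else c2)
        rep[locus] = canonical(union) if union else MISSING
    return ReplicateSet(
        sample_id=f"MIX:{g1.sample_id}+{g2.sample_id}",
        replicates=[dict(rep) for _ in range(n_replicates)],
    )


def apply_lab_frame(table: GenotypeTable, offsets: Mapping) -> GenotypeTable:
    """Shift every allele size by its locus offset (another lab's frame).

    ``offsets`` must cover every locus in the table (0 allowed); values are
    integers, or :class:`~strpanel.calibration.SplitOffset` for dual-class
    sex markers.  Raises if a shift would drive a size non-positive.
    """
    for name in table.locus_names:
        if name not in offsets:
            raise KeyError(f"no offset for locus {name!r}")
    individuals = []
    for g in table.individuals:
        calls = {n: shift_call(c, offsets[n]) for n, c in g.calls.items()}
        individuals.append(
            MultilocusGenotype(
                sample_id=g.sample_id,
                individual_id=g.individual_id,
                calls=calls,
                sex=g.sex,
                source=g.source,
            )
        )
    loci = []
    for l in table.loci:
        off = offsets[l.name]
        if isinstance(off, SplitOffset):
            universe = frozenset(
                a + (off.low if a < off.threshold else off.high)
                for a in l.allele_universe
            )
        else:
            universe = frozenset(a + off for a in l.allele_universe)
        loci.append(
            LocusDefinition(
                name=l.name,
                allele_universe=universe,
                size_range_by_lab=dict(l.size_range_by_lab),
                origin=l.origin,
                multiplex_group=l.multiplex_group,
            )
        )
    return GenotypeTable(loci=loci, individuals=individuals,
                         groups=dict(table.groups))
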