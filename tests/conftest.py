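import numpy as np
import pytest

import strpanel as sp
from strpanel.genotypes import (
    MISSING,
    GenotypeTable,
    LocusDefinition,
    MultilocusGenotype,
    Origin,
    Sex,
    canonical,
)


@pytest.fixture(scope="session")
def abb_cfg():
    return sp.abb_like_config()


@pytest.fixture(scope="session")
def abb_table(abb_cfg):
    """One ABB-like population draw (113 individuals, 13 loci + sex marker)."""
    return sp.sample_population(abb_cfg)


def make_random_table(seed, with_sex_marker=True, with_groups=True):
    """A small random genotype table with missing calls, for I/O properties."""
    rng = np.random.default_rng(seed)
    n_loci = int(rng.integers(1, 6))
    loci = []
    universes = {}
    for i in range(n_loci):
        base = int(rng.integers(80, 250))
        alleles = sorted(
            int(base + 2 * k) for k in range(int(rng.integers(2, 5)))
        )
        name = f"L{i}"
        universes[name] = alleles
        loci.append(
            LocusDefinition(name=name, allele_universe=frozenset(alleles))
        )
    if with_sex_marker:
        loci.append(
            LocusDefinition(
                name="SEXM",
                allele_universe=frozenset({150, 200}),
                origin=Origin.SEX_MARKER,
            )
        )
    n_ind = int(rng.integers(1, 12))
    individuals = []
    groups = {}
    for j in range(n_ind):
        calls = {}
        for name, alleles in universes.items():
            if rng.random() < 0.15:
                calls[name] = MISSING
            else:
                calls[name] = canonical(rng.choice(alleles, size=2))
        sex = Sex.UNKNOWN
        if with_sex_marker:
            if rng.random() < 0.5:
                sex, call = Sex.F, (150, 150)
            else:
                sex, call = Sex.M, (150, 200)
            calls["SEXM"] = canonical(call) if rng.random() > 0.1 else MISSING
            if calls["SEXM"] is MISSING:
                sex = Sex.UNKNOWN
        sid = f"S{j:03d}"
        individuals.append(
            MultilocusGenotype(sample_id=sid, calls=calls, sex=sex)
        )
        if with_groups:
            groups[sid] = "p1" if rng.random() < 0.5 else "p2"
    if with_groups and len(set(groups.values())) < 2:
        groups = {}
    return GenotypeTable(loci=loci, individuals=individuals,
                         groups=groups if with_groups else {})
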