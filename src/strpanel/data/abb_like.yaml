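# Simulation profile emulating the Apennine brown bear (ABB) reference
# population: 13 autosomal STR loci with 2-3 alleles each, published per-locus
# expected heterozygosity and replicate-level error rates, four PCR replicates
# per non-invasive sample, and two laboratory size frames related by constant
# per-locus offsets (add `offset` to Lab2 scores to obtain Lab3 scores).
#
# `published` blocks carry the literature-reported per-locus summary values
# for the reference population (effective allele number ne, observed
# heterozygosity ho, Shannon index shannon_i, identity probabilities pid /
# pidsib); they parameterize and cross-check analyses, they are never outputs.
name: abb_like
n_individuals: 113
sib_family_fraction: 0.2
n_replicates: 4
missing_rate: 0.05
frame: Lab3
seed: 0

sex_marker:
  name: AMG
  x_size: 158
  y_size: 212
  range_lab2: [204, 250]
  range_lab3: [158, 212]
  offsets: [-46, -38]   # X-fragment, Y-fragment (Lab2 -> Lab3)

loci:
  - name: CXX20
    origin: canid
    multiplex: 3
    n_alleles: 3
    he: 0.619
    ado: 0.085
    fa: 0.023
    range_lab2: [135, 139]
    range_lab3: [132, 136]
    offset: -3
    published: {ne: 2.6, ho: 0.655, shannon_i: 1.02, pid: 0.22, pidsib: 0.50, hwe: ns}
  - name: REN144A06
    origin: canid
    multiplex: 3
    n_alleles: 3
    he: 0.605
    ado: 0.076
    fa: 0.039
    range_lab2: [109, 129]
    range_lab3: [110, 130]
    offset: 1
    published: {ne: 2.5, ho: 0.670, shannon_i: 0.99, pid: 0.24, pidsib: 0.51, hwe: ns}
  - name: G1D
    origin: ursid
    multiplex: 2
    n_alleles: 3
    he: 0.573
    ado: 0.0
    fa: 0.0
    range_lab2: [172, 186]
    range_lab3: [100, 114]
    offset: -72
    published: {ne: 2.3, ho: 0.670, shannon_i: 0.95, pid: 0.25, pidsib: 0.53, hwe: ns}
  - name: Mu51
    origin: ursid
    multiplex: 1
    n_alleles: 3
    he: 0.560
    ado: 0.013
    fa: 0.0
    range_lab2: [206, 214]
    range_lab3: [114, 122]
    offset: -92
    published: {ne: 2.2, ho: 0.554, shannon_i: 0.94, pid: 0.26, pidsib: 0.53, hwe: ns}
  - name: G10B
    origin: ursid
    multiplex: 2
    n_alleles: 3
    he: 0.513
    ado: 0.159
    fa: 0.0
    range_lab2: [140, 156]
    range_lab3: [112, 128]
    offset: -28
    published: {ne: 2.0, ho: 0.518, shannon_i: 0.75, pid: 0.36, pidsib: 0.58, hwe: ns}
  - name: G10C
    origin: ursid
    multiplex: 1
    n_alleles: 3
    he: 0.501
    ado: 0.0
    fa: 0.0
    range_lab2: [197, 207]
    range_lab3: [95, 105]
    offset: -102
    published: {ne: 2.0, ho: 0.509, shannon_i: 0.71, pid: 0.37, pidsib: 0.59, hwe: ns}
  - name: Mu59
    origin: ursid
    multiplex: 2
    n_alleles: 2
    he: 0.488
    ado: 0.0
    fa: 0.0
    range_lab2: [229, 235]
    range_lab3: [101, 107]
    offset: -128
    published: {ne: 1.9, ho: 0.554, shannon_i: 0.68, pid: 0.38, pidsib: 0.60, hwe: ns}
  - name: Mu11
    origin: ursid
    multiplex: 1
    n_alleles: 3
    he: 0.456
    ado: 0.071
    fa: 0.0
    range_lab2: [188, 196]
    range_lab3: [88, 96]
    offset: -100
    published: {ne: 1.8, ho: 0.333, shannon_i: 0.67, pid: 0.39, pidsib: 0.62, hwe: "p<0.05"}
  - name: Mu05
    origin: ursid
    multiplex: 1
    n_alleles: 2
    he: 0.459
    ado: 0.058
    fa: 0.0
    range_lab2: [135, 137]
    range_lab3: [135, 137]
    offset: 0
    published: {ne: 1.8, ho: 0.500, shannon_i: 0.65, pid: 0.40, pidsib: 0.62, hwe: ns}
  - name: G10L
    origin: ursid
    multiplex: 2
    n_alleles: 2
    he: 0.439
    ado: 0.052
    fa: 0.0
    range_lab2: [157, 163]
    range_lab3: [148, 154]
    offset: -9
    published: {ne: 1.7, ho: 0.491, shannon_i: 0.63, pid: 0.41, pidsib: 0.63, hwe: ns}
  - name: Mu50
    origin: ursid
    multiplex: 1
    n_alleles: 2
    he: 0.448
    ado: 0.0
    fa: 0.0
    range_lab2: [132, 136]
    range_lab3: [100, 104]
    offset: -32
    published: {ne: 1.8, ho: 0.429, shannon_i: 0.64, pid: 0.41, pidsib: 0.63, hwe: ns}
  - name: G10P
    origin: ursid
    multiplex: 1
    n_alleles: 2
    he: 0.207
    ado: 0.083
    fa: 0.0
    range_lab2: [159, 171]
    range_lab3: [152, 164]
    offset: -7   # the ranges imply -7; see docs/methods.md on the sign
    published: {ne: 1.2, ho: 0.180, shannon_i: 0.36, pid: 0.65, pidsib: 0.81, hwe: ns}
  - name: Mu15
    origin: ursid
    multiplex: 2
    n_alleles: 2
    he: 0.170
    ado: 0.0
    fa: 0.035
    range_lab2: null        # not scored at Lab2
    range_lab3: [117, 121]
    offset: null
    published: {ne: 1.2, ho: 0.188, shannon_i: 0.31, pid: 0.71, pidsib: 0.84, hwe: ns}

# The four marker subsets compared in the reference study, plus the proposed
# routine panel (11 ursid loci + CXX20, the canid locus less prone to errors).
panels:
  shared9: [G1D, Mu51, G10B, G10C, Mu59, Mu11, Mu05, G10L, Mu50]
  lab2_11: [CXX20, REN144A06, G1D, Mu51, G10B, G10C, Mu59, Mu11, Mu05, G10L, Mu50]
  lab3_11: [G1D, Mu51, G10B, G10C, Mu59, Mu11, Mu05, G10L, Mu50, G10P, Mu15]
  complete13: [CXX20, REN144A06, G1D, Mu51, G10B, G10C, Mu59, Mu11, Mu05, G10L,
               Mu50, G10P, Mu15]
  proposed12: [CXX20, G1D, Mu51, G10B, G10C, Mu59, Mu11, Mu05, G10L, Mu50, G10P,
               Mu15]
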