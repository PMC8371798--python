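"""Draw a synthetic ABB-like bear population and check its diversity profile.

The packaged profile emulates the Apennine brown bear reference population:
113 individuals, 13 STR loci with 2-3 alleles each, a fifth of the sample in
full-sib pairs, and per-locus expected heterozygosity matching the published
values.
"""

import strpanel as sp

cfg = sp.abb_like_config(seed=1)
table = sp.sample_population(cfg)

print(f"simulated {len(table.individuals)} individuals "
      f"at {len(table.autosomal_loci)} autosomal loci (+ sex marker)\n")
print(f"{'locus':<10} {'target He':>9} {'observed He':>11}")
for locus in cfg.loci:
    fr = sp.allele_frequencies(table, locus.name)
    he = 1 - sum(v * v for v in fr.freqs.values())
    target = 1 - sum(f * f for f in locus.frequencies)
    print(f"{locus.name:<10} {target:>9.3f} {he:>11.3f}")

print("\nObserved He fluctuates around its target with SD ~ 0.02 at n=113;")
print("the configured frequencies hit the published He values exactly.")
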