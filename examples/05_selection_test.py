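"""Nei-Gojobori dN/dS and the Z-test of positive selection.

Simulates a codon alignment in which antigen-binding-site (ABS) codons
accumulate nonsynonymous changes three times faster than background, then
estimates dN and dS per partition with codon-bootstrap standard errors.
A significant one-tailed Z at ABS but not elsewhere is the classical
signature of historical positive selection on antigen presentation.
"""

import numpy as np

from mhcamp.selection import mean_rates, z_test

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in STOPS]

rng = np.random.default_rng(42)
n_codons = 62
abs_mask = np.zeros(n_codons, dtype=bool)
abs_mask[rng.choice(n_codons, 15, replace=False)] = True  # 15 ABS codons

CODE = {}
from Bio.Data.CodonTable import standard_dna_table as _table

CODE.update(_table.forward_table)

ancestor = list(rng.choice(SENSE, n_codons))
sequences = []
for _ in range(10):
    codons = []
    for i, codon in enumerate(ancestor):
        new = codon
        if abs_mask[i] and rng.random() < 0.5:
            # selection at ABS: fix an amino-acid-changing mutation
            for _ in range(50):
                j = int(rng.integers(3))
                alt = rng.choice([x for x in "ACGT" if x != new[j]])
                mutant = new[:j] + alt + new[j + 1:]
                if mutant not in STOPS and CODE[mutant] != CODE[new]:
                    new = mutant
                    break
        elif rng.random() < 0.10:
            # neutral background drift
            j = int(rng.integers(3))
            alt = rng.choice([x for x in "ACGT" if x != new[j]])
            mutant = new[:j] + alt + new[j + 1:]
            if mutant not in STOPS:
                new = mutant
        codons.append(new)
    sequences.append("".join(codons))

print("partition   dN(SE)        dS(SE)        Z      P(one-tailed)")
for partition in ("all", "ABS", "nonABS"):
    est = mean_rates(sequences, abs_mask, partition, bootstrap_reps=1000, seed=7)
    z = z_test(est)
    print(f"{partition:<10}  {est.dN:.3f}({est.SE_dN:.3f})  "
          f"{est.dS:.3f}({est.SE_dS:.3f})  {z.z:5.2f}  {z.p:.4f}")
print("(dN > dS with small P at ABS indicates positive selection there)")
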