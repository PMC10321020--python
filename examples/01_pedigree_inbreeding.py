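"""Pedigree inbreeding on classical textbook matings.

Builds a five-animal pedigree containing a full-sib mating, computes the
Meuwissen-Luo inbreeding coefficients and the numerator relationship
matrix, and prints both.  The offspring of full sibs has F = 0.25 (its
parents share half their genes, so its two genome copies are identical by
descent a quarter of the time), and the matrix diagonal is 1 + F.
"""

import inbredscope as ib

ped = ib.Pedigree.from_records([
    ("A", "0", "0", 2000), ("B", "0", "0", 2000),
    ("C", "A", "B", 2001), ("D", "A", "B", 2001),
    ("E", "C", "D", 2002),
])

f = ib.f_ped(ped)
print("Pedigree inbreeding coefficients:")
print(f.to_string())

A = ib.numerator_relationship_matrix(ped)
print("\nNumerator relationship matrix (diag = 1 + F):")
print(A.round(3).to_string())

print("\nPer-cohort mean inbreeding:")
import pandas as pd
print(ib.mean_f_by_cohort(f, pd.Series(ped.birth_year, index=ped.ids)).to_string(index=False))
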