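"""Fingerprint evaluation: nearest-known-ligand similarity and scaffolds.

Compares a "generated" set against a reference ligand set with ECFP4
(1024-bit, radius-2) Tanimoto nearest neighbors, then counts the most
frequent Bemis-Murcko scaffolds.
"""

import numpy as np

import pcmolkit as pk

spec = pk.FixtureSpec(num_families=2, targets_per_family=2,
                      count_range=(30, 30), seed=5)
sets = pk.make_ligands(spec)
reference = [r.smiles for r in sets[0].records]
# mix of in-family molecules, out-of-family molecules, and one bad string
generated = ([r.smiles for r in sets[1].records[:10]]
             + [r.smiles for r in sets[2].records[:10]]
             + ["C1CC("])

report = pk.nearest_tanimoto(generated, reference)
print("summary:", {k: round(v, 3) for k, v in report.summary().items()})
# max_tanimoto near 1 means the molecule is (close to) a known ligand;
# fraction_novel counts canonical forms absent from the reference set
print("max Tanimoto quartiles:", [round(q, 3) for q in report.quartiles])

sc = pk.murcko_scaffold_counts([s for s in generated[:-1]], top_k=4)
print("top Murcko scaffolds (framework, count):")
for s, c in sc.top:
    print(f"  {s}  x{c}")
print(f"acyclic molecules: {sc.acyclic_count}, invalid: {sc.invalid_count}")
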