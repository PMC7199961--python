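"""Hybridization energy of miRNA:site duplexes and the candidate filter.

The scanner only forwards candidate sites whose duplex minimum free
energy (MFE) is at or below -20 kcal/mol to the classifier; everything
else is considered too unstable to be a target.  Here we compare a
perfectly complementary site, a seed-only match and a random site.
"""

import numpy as np

from chimeranet import SequenceRecord, duplex_mfe, filter_candidates
from chimeranet.synthetic_data import reverse_complement

rng = np.random.default_rng(7)
mirna = "UGAGGUAGUAGGUUGUAUAGUU"

perfect = reverse_complement(mirna)
seed_only = "GGCAUUCGAU" + reverse_complement(mirna[1:8]) + "CCAUGGAACGAUU"
random_site = "".join("AUGC"[i] for i in rng.integers(0, 4, 40))

candidates = []
for name, site in [("perfect", perfect), ("seed-only", seed_only), ("random", random_site)]:
    result = duplex_mfe(mirna, site)
    candidates.append((name, result))
    print(f"{name:10s} site: MFE = {result.mfe:7.2f} kcal/mol, "
          f"{len(result.pairs)} base pairs")
    print(f"           {result.pairing}")

kept = filter_candidates(candidates, threshold=-20.0)
print(f"\nsurvivors of the -20 kcal/mol filter: {[name for name, _ in kept]}")
print("(only sites stable enough to plausibly hybridize reach the CNN)")
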