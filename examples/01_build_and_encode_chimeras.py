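"""Build a miRNA:target-site chimera and encode it for the classifier.

A chimera is the miRNA concatenated 5'->3' with a candidate target site,
padded to 110 nt with random bases that cannot pair with the miRNA over
four or more contiguous positions, then one-hot encoded (A,U,G,C columns)
into the 110 x 4 matrix the network consumes.
"""

import numpy as np

from chimeranet import (
    SequenceRecord,
    concatenate_chimera,
    encode_one_hot,
    pad_chimera,
)

mirna = SequenceRecord("example-mir", "UGAGGUAGUAGGUUGUAUAGUU")
site = "AACUAUACAACCUACUACCUCAACCUUGGAGAUAUUCCAGAAGG"

raw = concatenate_chimera(mirna, site)
print(f"miRNA ({len(mirna.seq)} nt) + site ({len(site)} nt) -> raw chimera {len(raw)} nt")

full = pad_chimera(raw, mirna.seq, np.random.default_rng(0))
print(f"padded to {len(full)} nt; pad = {full[len(raw):]!r}")

matrix = encode_one_hot(full)
print(f"one-hot matrix: shape {matrix.shape}, every row sums to "
      f"{int(matrix.sum(axis=1).min())} (exactly one channel per base)")
print("first four rows (bases", full[:4], "):")
print(matrix[:4].astype(int))
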