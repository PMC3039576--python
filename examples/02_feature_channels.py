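"""Build the five feature channels for a toy set of proteins.

Shows the amino-acid and di-peptide composition of one sequence and the
shape/sparsity of the binary GO-aspect matrices.
"""

import numpy as np

from gotlm import build_channels, generate, preset
from gotlm.features import AA_ALPHABET

dataset = generate(preset("separable", seed=7))
channels = build_channels(dataset.records, dataset.annotations)

seq = dataset.records[0].sequence
aa = channels["AA"].matrix[0]
top = np.argsort(aa)[::-1][:5]
print(f"protein {dataset.records[0].id} ({len(seq)} residues)")
print("top amino-acid frequencies:",
      {AA_ALPHABET[i]: round(float(aa[i]), 3) for i in top})
print("composition rows sum to:", round(float(aa.sum()), 12))

for name in ("AA", "diAA", "P", "F", "C"):
    m = channels[name].matrix
    print(f"channel {name}: shape {m.shape}, nonzero fraction {np.count_nonzero(m)/m.size:.3f}")
# AA/diAA rows are probability vectors; the GO channels are sparse 0/1
# indicators over the training vocabulary of each aspect.
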