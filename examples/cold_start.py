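"""Score a cold-start entity: a disease with no known microbes yet.

The combined score sums a disease-space and a microbe-space projection.
For a disease whose association row is empty, the microbe-space projection
is zero by convention -- but the disease-space projection still works,
because it only needs the disease's similarity to other diseases and their
association columns. The new disease therefore still receives a usable
ranking over microbes instead of being unscorable.
"""

import numpy as np

from ncpmda import AssociationNetwork, predict

# three annotated diseases plus one brand-new disease (all-zero row)
A = np.array(
    [
        [1, 1, 0, 0, 1, 0],
        [1, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 1, 1],
        [0, 0, 0, 0, 0, 0],   # the new disease
    ]
)
net = AssociationNetwork(
    ("ulcerative colitis", "Crohn's disease", "psoriasis", "NEW disease"),
    tuple(f"microbe_{j}" for j in range(6)),
    A,
)

S = predict(net).S
new = net.disease_index["NEW disease"]
order = np.argsort(-S[new])
print("ranking of microbes for the cold-start disease:")
for j in order:
    print(f"  {net.microbes[j]:<10} score {S[new, j]:.4f}")
print("\nnon-zero scores despite an empty association row: the ranking is "
      "driven\nentirely by the disease-space projection (similarity to "
      "annotated diseases).")
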