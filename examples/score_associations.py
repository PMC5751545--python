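"""Score candidate microbes for diseases in a small curated edge list.

Builds a toy disease-microbe association network of the kind a curated
database exports (two tab-separated label columns), scores every pair with
network consistency projection, and prints the top novel candidates per
disease. Scores lie in [0, 1]; a high score for an unknown pair means the
pair is consistent with the similarity structure of the known network --
the disease's similar diseases are already associated with the microbe, or
the microbe's similar microbes with the disease.
"""

import numpy as np

from ncpmda import build_network, EdgeRecord, predict

EDGES = [
    ("colon cancer", "Clostridium difficile"),
    ("colon cancer", "Helicobacter pylori"),
    ("colon cancer", "Bacteroides"),
    ("type 2 diabetes", "Helicobacter pylori"),
    ("type 2 diabetes", "Prevotella"),
    ("type 2 diabetes", "Lactobacillus"),
    ("asthma", "Clostridium difficile"),
    ("asthma", "Firmicutes"),
    ("irritable bowel syndrome", "Lactobacillus"),
    ("irritable bowel syndrome", "Bacteroides"),
]

net, report = build_network(EdgeRecord(d, m) for d, m in EDGES)
print(
    f"network: {report.nd} diseases x {report.nm} microbes, "
    f"{report.n_associations} known associations"
)

scores = predict(net)
A = np.asarray(net.A)
print("\ntop novel candidate per disease (known pairs excluded):")
for i, disease in enumerate(net.diseases):
    unknown = np.where(A[i] == 0)[0]
    best = unknown[np.argmax(scores.S[i, unknown])]
    print(f"  {disease:<26} -> {net.microbes[best]:<24} "
          f"score {scores.S[i, best]:.4f}")
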