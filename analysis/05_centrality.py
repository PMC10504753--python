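#!/usr/bin/env python
"""Node centrality: which symptoms hold the comorbidity network together.

Computes expected influence (EI), bridge expected influence (bEI) across
the anxiety/depression boundary, and nodewise predictability for the
estimated network, and names the top central and bridge symptoms.
"""

from pathlib import Path

import pandas as pd

from symptomnet.centrality import centrality_table
from symptomnet.ggm import GGMNetwork
from symptomnet.reference import SYMPTOM_LABELS

scratch = Path("scratch/analysis")
results = Path("results/analysis")

net = GGMNetwork.from_json(results / "network.json")
analysis = pd.read_csv(scratch / "screened.csv")
table = centrality_table(net, analysis)
table.round(4).to_csv(results / "centrality.tsv", sep="\t", index_label="node")
print(table.round(3).to_string())

top_ei = table["EI"].nlargest(3)
top_bei = table["bEI"].nlargest(3)
print("\ntop central symptoms:",
      ", ".join(f"{nd} ({SYMPTOM_LABELS[nd]})" for nd in top_ei.index))
print("top bridge symptoms:",
      ", ".join(f"{nd} ({SYMPTOM_LABELS[nd]})" for nd in top_bei.index))
print(f"mean predictability: {table['predictability'].mean():.2f}")
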