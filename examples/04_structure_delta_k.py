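"""Admixture-model clustering with Delta-K model choice.

Fits the Gibbs sampler to a three-population synthetic panel for
K = 1..5 with replicated runs, prints the Delta-K table and the
per-cluster membership summary at the selected K.
"""

import numpy as np

from gbscore import simulate as sim
from gbscore import structure as st

model = sim.simulate_populations(3, 150, fst=0.3, seed=41)
accessions = sim.simulate_accessions(model, 45, seed=42)
X = np.array([a.haplotype for a in accessions], dtype=float)

cfg = st.StructureConfig(k_range=(1, 5), n_runs=3,
                         burnin=1000, reps=2500, seed=43)
runs = st.run_k_range(X, cfg)
dk = st.evanno(runs)
print(dk.table.round(2))
print(f"selected K           : {dk.selected_k}")

aligned = st.align_labels(runs[dk.selected_k])
consensus = np.mean([r.Q for r in aligned], axis=0)
assignment = st.assign(consensus, threshold=0.8,
                       sample_ids=[a.accession_id for a in accessions])
shares = assignment.attrs["cluster_mean_pct"]
print("mean membership      :",
      " / ".join(f"{s:.1f}%" for s in shares))
print(f"admixed (<0.8)       : "
      f"{(assignment['label'] == 'admixed').sum()} of {len(assignment)}")
# Delta K peaks at the true number of populations; the membership
# shares correspond to the per-cluster percentages reported for
# germplasm panels.
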