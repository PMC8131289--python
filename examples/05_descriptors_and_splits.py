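"""Real-structure path: RDKit descriptors, exclusion rules, fingerprint split.

Generates a campaign *with SMILES*, computes the open 2D descriptor battery,
applies the three exclusion rules, and builds a fingerprint-based cluster
split plus a time split.
"""

import numpy as np

import kpuubrain as kb
from kpuubrain.assays import derive_table
from kpuubrain.features import compute_descriptors, prepare_descriptors
from kpuubrain.validation import cluster_split, time_split

ds = kb.generate_dataset(kb.GeneratorConfig(
    n_compounds=200, seed=3, emit_smiles=True))
derived = derive_table(ds.table)
y = np.log10(derived["kpuu"].to_numpy())

m = compute_descriptors(list(derived["smiles"]), list(derived["compound_id"]))
print(f"{len(m.descriptor_names)} descriptors computed for "
      f"{len(m.compound_ids)} structures "
      f"({len(m.failed_structures)} unparseable)")

split = cluster_split(list(derived["smiles"]), y, seed=3)
n_clusters = len(set(split.cluster_ids))
print(f"fingerprint leader clustering at Tanimoto 0.7: {n_clusters} clusters; "
      f"{split.test_idx.size} test compounds, none sharing a cluster with training")

prepared = prepare_descriptors(m.to_frame(), y, split.train_idx,
                               count_type=m.count_type)
rules = {}
for _, rule in prepared.excluded:
    rules[rule] = rules.get(rule, 0) + 1
print(f"exclusion rules dropped {sum(rules.values())} descriptors: {rules}")
print(f"{len(prepared.descriptor_names)} retained, standardized on training rows")

tsplit = time_split(derived["assay_date"])
print(f"time split cutoff {tsplit.params['date_cutoff']}: "
      f"{tsplit.train_idx.size} train / {tsplit.test_idx.size} test")
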