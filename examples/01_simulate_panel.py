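"""Generate a synthetic cell-line panel with known ground truth.

The panel emulates a phosphoproteomics screen: 24 cell lines measured in
triplicate over 1000 features, with 24 drugs in 6 response clusters. Each
drug has 20 planted sensitivity and 20 planted resistance markers whose
abundance rises or falls linearly with the latent drug sensitivity (= AAC).
"""

import drugrank as dr

spec = dr.reference_settings()
omics, responses, truth = dr.generate_panel(spec)

print(f"omics matrix : {omics.values.shape[0]} features x {omics.values.shape[1]} replicates")
print(f"cell lines   : {len(omics.cell_line_ids)} ({spec.n_replicates} replicates each)")
print(f"missingness  : {omics.missingness():.1%} of entries")
print(f"responses    : {responses.aac.shape[0]} drugs x {responses.aac.shape[1]} lines, "
      f"AAC in [{responses.aac.min().min():.2f}, {responses.aac.max().max():.2f}]")

drug = responses.drug_ids[0]
print(f"\n{drug}: cluster {truth.clusters[drug]}, "
      f"{len(truth.sensitivity_markers[drug])} sensitivity + "
      f"{len(truth.resistance_markers[drug])} resistance markers planted")
print("AAC of first 5 lines:", responses.aac.loc[drug].iloc[:5].round(3).to_dict())
# Higher AAC = stronger anti-proliferative effect; markers planted for this
# drug track exactly these values (plus measurement noise).
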