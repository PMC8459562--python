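"""Generate a synthetic drug-target dataset with planted block structure.

Drugs and targets are assigned to latent blocks; interactions are common
within a block (pi_in) and rare across blocks (pi_out), and similarity
scores are elevated for same-block pairs — the "similar drugs hit similar
targets" regularity that network-based interaction prediction exploits.
"""

import dtiwalk

cfg = dtiwalk.SyntheticConfig(
    m=60, n=60, B=4, pi_in=0.5, pi_out=0.01, seed=11
)
net, drug_sim, target_sim = dtiwalk.generate_block_dataset(cfg)
summary = dtiwalk.summarize_dataset(net)

print(summary.format())
# known / unknown counts the class imbalance the classifier must survive;
# the sparsity ratio (known/unknown) is the positive:negative class ratio.
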