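"""Codon-position bias of editing sites versus selection strength.

Under the mutation-selection model of editing-site origin, genes under
stronger selection should accumulate relatively more third-position than
second-position C insertions.  Simulates genes across the conservation range
and tabulates R = N3/N2 per conservation group with propagated counting
errors.
"""

import numpy as np

from myxoedit import codon_bias, synthetic

genes = []
for i in range(12):
    target = 0.95 if i % 2 == 0 else 0.70
    truth = synthetic.simulate_gene_pair(
        synthetic.SimulationConfig(protein_len_range=(400, 450)),
        np.random.default_rng([1, i]),
        f"gene{i}",
        conservation_target=target,
    )
    genes.append((truth.identity[1], [truth.transcript_a, truth.transcript_b]))

for k in (2, 4):
    df = codon_bias.group_and_trend(genes, n_groups=k)
    print(f"--- {k} conservation groups")
    print(df.round(3).to_string(index=False))
print(
    "trend beyond combined 1-sigma errors:",
    codon_bias.group_and_trend(genes, n_groups=2).attrs["monotone_beyond_1sigma"],
)
# Each row pools unambiguous C-site counts (N1, N2, N3) of the genes whose
# second-codon-position conservation falls in [lo, hi); R rises with
# conservation because second-position insertions almost always change the
# amino acid and are purged under strong selection.
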