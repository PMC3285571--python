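"""How much flanking context would a sequence-reading editing machinery need?

Builds a synthetic edited transcriptome and reports (a) the largest single-
sided k-mer that occurs both next to an unambiguous C-insertion site and at a
definitely-non-edited locus, and (b) the frontier of non-unique straddling
m+n contexts.  Any recognition region would have to exceed these sizes.
"""

from myxoedit import motifs, synthetic

cfg = synthetic.SimulationConfig(n_genes=8, protein_len_range=(200, 300))
truths = synthetic.simulate_transcriptome(cfg, seed=12)
tx = motifs.Transcriptome([t.transcript_a for t in truths])

for level in ("edited", "unedited"):
    for side in ("upstream", "downstream"):
        k, witnesses = motifs.max_nonunique_flank(tx, side, level)
        w = sorted(witnesses)[0] if witnesses else "-"
        print(f"{level:9s} {side:10s}: largest non-unique k = {k}  (e.g. {w})")
    frontier, sufficient = motifs.specificity_frontier(tx, level)
    print(f"{level:9s} m+n frontier : {sorted(frontier)}")
    print(f"{level:9s} minimal sufficient regions : {sorted(sufficient)}")
# A frontier entry (m, n) means some m-upstream/n-downstream context of a
# real site recurs at a non-edited locus, so recognition needs more than
# m+n positions; the minimal sufficient set lists the smallest contexts that
# were always unique in this transcriptome.
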