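"""Score substrate tail motifs with the SEG compositional complexity.

Substrate tails engaging the ClpX pore differ in how 'slippery' they are;
low-complexity regions (polyG, GA/GS repeats) have been proposed to predict
slipperiness.  The score below is the Shannon entropy (bits) of each motif's
residue composition; a motif above 2.5 bits counts as high complexity.
"""

from dwellscope import complexity
from dwellscope.sequence_complexity import results_to_dataframe

MOTIFS = {
    "Ref11": "GLGARSAGITH",      # reference tail, high complexity, hydrophobic
    "polyG11": "GGGGGGGGGGG",    # homopolymer: complexity 0 by definition
    "GA11": "AGAGGAAGAGG",       # glycine-alanine repeat
    "GS11": "SGSGGSSGSGG",       # glycine-serine repeat (same composition class)
    "SUMO11": "AKPSTEDLGDK",     # polar/charged high-complexity motif
    "SUMO11_rev": "KDGLDETSPKA",  # reversed: identical composition, same score
}

results = [complexity(seq, name=name) for name, seq in MOTIFS.items()]
print(results_to_dataframe(results).to_string(index=False))
print(
    "\nScores are bits of composition entropy; 'high' means > 2.5 bits."
    "\nGA11/GS11 tie at 0.99 and SUMO11_rev matches SUMO11 exactly because the"
    "\nscore depends only on residue counts, not order."
)
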