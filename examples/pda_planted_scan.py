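"""Phylogenetic discriminant analysis on a planted synthetic alignment.

Generates an annotated alignment of two phylogenetic groups (100 sequences
each, 25 columns) in which three planted columns carry group-specific
residues, scans all C(25,3) = 2300 position triplets, and reports which
positions the entropy-based selection recovers.
"""

import numpy as np

from pdakit import PDAConfig, PlantedMSASpec, make_grouped_msa, run_pda

spec = PlantedMSASpec(
    n_per_group={"bacteria": 100, "eukaryotes": 100},
    n_positions=25,
    planted_triplet=(3, 11, 19),
    purity=1.0,
    seed=1,
)
aln, ann, truth = make_grouped_msa(spec)
result = run_pda(aln, ann, PDAConfig())  # 5th-percentile reference, 3/10 sigma

print(f"scanned triplets:        {result.score_table.n_scanned}")
print(f"planted triplet H:       "
      f"{result.score_table.score_of(truth['planted_triplet']):.6f}")
print(f"reference H (5th pct):   {result.reference_H:.6f}")
print(f"selected triplets m:     {result.m_selected}")
top3 = sorted(int(i) for i in np.argsort(result.selection_frequency)[-3:])
print(f"top-3 positions:         {top3} (planted: {truth['planted_triplet']})")
print(f"positions beyond 10 sigma: {list(result.selected_positions[10.0])}")
print(f"null model: p_null = {result.null.p_null:.4f}, "
      f"sigma_p = {result.null.sigma_p:.4f}")
# A perfectly discriminating triplet scores H = 0 (each cluster contains a
# single group); its positions dominate the low-entropy triplets, far above
# the uniform-prior expectation 3/N_pos, and are called at 10 sigma.
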