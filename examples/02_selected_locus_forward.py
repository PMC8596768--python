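"""Forward-simulate a locus under divergent selection and compare to neutral.

Alternate alleles are favoured in the two demes (antagonistic pleiotropy,
s1 = s2 = 0.1) from 40,000 generations ago, acting on standing variation at
initial frequency 0.1. The model is rescaled (lambda = 10) so the forward
Wright-Fisher simulation runs at 1000 diploids per deme while preserving
4*N*mu, M = N*m, N*s and t/N.
"""

import numpy as np

from lsd import (
    SelectionRegime,
    rescale,
    simulate_locus,
    simulate_selected_locus,
    stats_vector,
    two_deme_im_model,
)
from lsd.selection import _literal_model

rng = np.random.default_rng(7)
model = two_deme_im_model()
params = {"M12": 5.0, "M21": 5.0}
sample_config = {"deme1": 20, "deme2": 20}

regime = SelectionRegime(s1=0.1, s2=0.1, t_onset=40_000.0, f1=0.1, f2=0.1)
small, regime_s = rescale(_literal_model(model, params), regime, 10.0)

locus, trajectory = simulate_selected_locus(
    small, None, regime_s, 5000, small.mutation_rate, sample_config, rng,
    return_trajectory=True,
)
neutral = simulate_locus(model, params, sample_config, 5000, rng)

sel_stats = stats_vector(locus, ["deme1", "deme2"])
neu_stats = stats_vector(neutral, ["deme1", "deme2"])
print("derived-allele frequency at sampling:",
      np.round(trajectory.freqs[-1], 3), "(deme1, deme2)")
print(f"F_ST selected locus: {sel_stats['fst_deme1_deme2']:.3f}")
print(f"F_ST neutral locus:  {neu_stats['fst_deme1_deme2']:.3f}")
print()
print("Divergent selection keeps alternate alleles at high frequency in their")
print("home demes; the fully linked 5-kb window inherits the deep split, so")
print("the selected locus shows far higher F_ST than the neutral background.")
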