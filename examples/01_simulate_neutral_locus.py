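"""Simulate a neutral 5-kb locus under a two-deme IM model and inspect it.

The model: two demes of 10,000 diploids exchanging M12 = M21 = 5 migrants
per generation, mutation rate 5e-7 per bp per generation. A locus is a
non-recombining window with a single shared genealogy.
"""

import numpy as np

from lsd import simulate_locus, stats_vector, two_deme_im_model

model = two_deme_im_model()  # N1 = N2 = 10,000, M12/M21 free
params = {"M12": 5.0, "M21": 5.0}
sample_config = {"deme1": 20, "deme2": 20}  # haploid genomes per deme

locus = simulate_locus(model, params, sample_config, locus_length=5000,
                       rng=np.random.default_rng(1))
print(f"sampled {locus.n_samples} haplotypes, {locus.n_sites} segregating sites")

stats = stats_vector(locus, ["deme1", "deme2"])
print(stats.round(4).to_string())
print()
print("S_* count segregating sites per deme; pi_* and thetaW_* are per-locus")
print("diversity; fst/dxy measure divergence between the demes. At M = 5 the")
print("demes are nearly panmictic, so F_ST is small (a few percent).")
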