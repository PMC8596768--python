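"""Build a small ABC reference table and a per-locus migration posterior.

The reference table pairs parameter draws (log10 M12, log10 M21 ~ U[-4, 3])
with single-locus summary statistics. For an observed locus, the closest
simulations in PLS space are retained, a linear-Gaussian model is fitted and
the posterior over (log10 M12, log10 M21) is evaluated on a 33 x 33 grid.
A realistic analysis uses 50,000+ simulations; 4000 keeps this demo fast.
"""

import numpy as np

from lsd import (
    build_reference_table,
    default_migration_priors,
    fit_transform,
    locus_posterior,
    simulate_locus,
    stats_vector,
    two_deme_im_model,
)

rng = np.random.default_rng(3)
model = two_deme_im_model()
priors = default_migration_priors()
sample_config = {"deme1": 20, "deme2": 20}

print("simulating 4000-row reference table (about a half minute) ...")
table = build_reference_table(model, priors, 4000, sample_config, 5000, rng,
                              sfs_bins=4)
transform = fit_transform(table, 8)

locus = simulate_locus(model, {"M12": 5.0, "M21": 5.0}, sample_config, 5000, rng)
obs = stats_vector(locus, ["deme1", "deme2"], sfs_bins=4)
grid = locus_posterior(table, transform, obs, n_retain=400)

mode = grid.cell_values(grid.mode())
marg12 = grid.mass.sum(axis=1)
lo, hi = grid.axes[0][np.searchsorted(np.cumsum(marg12), [0.05, 0.95])]
print(f"posterior mode: log10 M12 = {mode[0]:.2f}, log10 M21 = {mode[1]:.2f}")
print(f"90% of the M12 marginal lies in [{lo:.2f}, {hi:.2f}] (truth: 0.70)")
print()
print("A single locus constrains the migration rates only loosely - the")
print("posterior is broad - but it correctly excludes the low-migration")
print("regime; the scan gains its precision by combining many loci.")
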