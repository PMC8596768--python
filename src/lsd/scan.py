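"""The scan core: neutral point estimate, per-locus HPD p-values and asymmetry.

The scan proceeds in two steps. First, the neutral demographic point estimate
``theta_hat = (log10 M12_hat, log10 M21_hat)`` is the arg-max over grid cells
of the summed log posterior densities of the putatively neutral loci (the
product-of-densities estimate). Second, every locus is assessed against
``theta_hat``:

* ``h_l`` — the smallest highest-posterior-density mass containing
  ``theta_hat`` (total mass of cells strictly denser than the ``theta_hat``
  cell); ``p_l = 1 - h_l``. For loci truly at ``theta_hat``, ``p_l`` is
  (conservatively) stochastically at least uniform and is read as a p-value
  against neutrality.
* ``sigma_l`` — the posterior mass where the ratio deviation
  ``log10 M21 - log10 M12`` falls below its neutral value (cells on the
  boundary contribute half their mass), and the asymmetry
  ``a_l = ln(sigma_l / (1 - sigma_l))``. A value of 0 reflects perfect
  symmetry of the joint posterior about the neutral ratio line.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abc_glm import (
    DENSITY_FLOOR,
    PosteriorGrid,
    ReferenceTable,
    StatTransform,
    locus_posterior,
    retention_size,
)

SIGMA_CLAMP = 1e-6  #: sigma is clamped to [eps, 1-eps] before the logit
LOG_FLOOR = log(DENSITY_FLOOR)


@dataclass
class NeutralEstimate:
    """The neutral parameter point estimate on the posterior grid."""

    cell: tuple  #: grid indices
    values: tuple  #: (log10 M12_hat, log10 M21_hat)
    log_density: np.ndarray  #: per-cell summed log densities (diagnostic)
    axis_names: list


def estimate_neutral(posteriors: Sequence[PosteriorGrid]) -> NeutralEstimate:
    """Product-of-densities point estimate over the neutral loci.

    ``theta_hat`` maximizes the sum over loci of log cell mass. Each locus's
    log mass is max-normalized before summation (a per-locus constant that
    leaves the arg max unchanged but keeps the sum within floating range) and
    per-cell sums are floored at ``log(1e-300)``; ties break toward the
    smallest flat cell index.
    """
    if not posteriors:
        raise ValueError("need at least one neutral posterior")
    ref = posteriors[0]
    total = np.zeros(ref.shape)
    for g in posteriors:
        if not ref.same_grid(g):
            raise ValueError("posterior grids do not match")
        logm = np.log(np.clip(g.mass, DENSITY_FLOOR, None))
        total += logm - logm.max()
    total = np.maximum(total, LOG_FLOOR)
    cell = tuple(int(i) for i in np.unravel_index(int(np.argmax(total)), total.shape))
    return NeutralEstimate(cell, ref.cell_values(cell), total, list(ref.axis_names))


def hpd_pvalue(posterior: PosteriorGrid, theta_hat: NeutralEstimate | tuple) -> tuple[float, float]:
    """(h_l, p_l): HPD mass containing theta_hat and its complement.

    ``h_l`` sums the mass of cells whose density strictly exceeds that of the
    ``theta_hat`` cell; equal-density cells are excluded, which makes a flat
    posterior yield ``h = 0, p = 1`` (the conservative direction).
    """
    cell = theta_hat.cell if isinstance(theta_hat, NeutralEstimate) else tuple(theta_hat)
    d0 = posterior.mass[cell]
    h = float(posterior.mass[posterior.mass > d0].sum())
    return h, 1.0 - h


def asymmetry_sigma(posterior: PosteriorGrid, theta_hat: NeutralEstimate | tuple) -> float:
    """Posterior mass with ``log10 M21 - log10 M12`` below its neutral value.

    Boundary cells (ratio deviation exactly neutral) contribute half their
    mass — the continuum integral puts zero mass on the boundary, so the grid
    needs an explicit, symmetric tie rule.
    """
    cell = theta_hat.cell if isinstance(theta_hat, NeutralEstimate) else tuple(theta_hat)
    ax1, ax2 = posterior.axes  # log10 M12, log10 M21
    diff = ax2[None, :] - ax1[:, None]
    d_hat = float(ax2[cell[1]] - ax1[cell[0]])
    span = max(abs(ax1[-1] - ax1[0]), abs(ax2[-1] - ax2[0]), 1.0)
    tol = 1e-9 * span
    below = diff < d_hat - tol
    on = np.abs(diff - d_hat) <= tol
    return float(posterior.mass[below].sum() + 0.5 * posterior.mass[on].sum())


def asymmetry_score(sigmas, mode: str = "per_locus"):
    """Logit asymmetry a = ln(sigma / (1 - sigma)) (natural log).

    ``per_locus`` returns one value per input sigma; ``aggregate_selected``
    applies the logit to the mean sigma over the designated loci. Sigmas are
    clamped to [1e-6, 1 - 1e-6] so the score stays finite.
    """
    s = np.asarray(sigmas, dtype=float)
    if s.size == 0:
        raise ValueError("empty sigma input")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("sigma values must lie in [0, 1]")
    if mode == "aggregate_selected":
        s = np.mean(s)
    elif mode != "per_locus":
        raise ValueError(f"unknown mode {mode!r}")
    s = np.clip(s, SIGMA_CLAMP, 1.0 - SIGMA_CLAMP)
    return np.log(s / (1.0 - s)) if np.ndim(s) else float(np.log(s / (1.0 - s)))


@dataclass
class ScanResult:
    """Everything the two-step scan produced for one set of observed loci."""

    records: pd.DataFrame  #: locus_id, mode_M12, mode_M21, h, p, sigma, a
    estimate: NeutralEstimate
    posteriors: list  #: per-locus PosteriorGrid, row-aligned with records


def compute_posteriors(
    stats: pd.DataFrame,
    table: ReferenceTable,
    transform: StatTransform,
    *,
    n_retain: int | None = None,
    grid_shape: tuple = (33, 33),
) -> list[PosteriorGrid]:
    """ABC-GLM posterior for every row of a per-locus statistics table."""
    if n_retain is None:
        n_retain = retention_size(len(table.params))
    return [
        locus_posterior(table, transform, stats.iloc[i], n_retain=n_retain, shape=grid_shape)
        for i in range(len(stats))
    ]


def records_from_posteriors(
    posteriors: Sequence[PosteriorGrid],
    estimate: NeutralEstimate,
    locus_ids: Sequence,
) -> pd.DataFrame:
    rows = []
    for lid, g in zip(locus_ids, posteriors):
        h, p = hpd_pvalue(g, estimate)
        sigma = asymmetry_sigma(g, estimate)
        mode = g.cell_values(g.mode())
        rows.append(
            {
                "locus_id": lid,
                "mode_M12": mode[0],
                "mode_M21": mode[1],
                "h": h,
                "p": p,
                "sigma": sigma,
                "a": asymmetry_score(sigma),
            }
        )
    return pd.DataFrame(rows)


def run_scan(
    stats: pd.DataFrame,
    table: ReferenceTable,
    transform: StatTransform,
    *,
    neutral_ids: Sequence | None = None,
    n_retain: int | None = None,
    grid_shape: tuple = (33, 33),
    posteriors: Sequence[PosteriorGrid] | None = None,
) -> ScanResult:
    """The full two-step scan over a per-locus statistics table.

    ``stats`` has one row per locus (index = locus id). ``neutral_ids``
    designates the putatively neutral subset used for ``theta_hat`` (default:
    all loci). Precomputed ``posteriors`` may be passed to re-run the second
    step under a different neutral subset without refitting.
    """
    if posteriors is None:
        posteriors = compute_posteriors(
            stats, table, transform, n_retain=n_retain, grid_shape=grid_shape
        )
    ids = list(stats.index)
    if neutral_ids is None:
        neutral_ids = ids
    neutral_set = set(neutral_ids)
    missing = neutral_set - set(ids)
    if missing:
        raise ValueError(f"neutral ids not in the scan set: {sorted(missing)[:5]}")
    neutral_posteriors = [g for lid, g in zip(ids, posteriors) if lid in neutral_set]
    estimate = estimate_neutral(neutral_posteriors)
    records = records_from_posteriors(posteriors, estimate, ids)
    return ScanResult(records, estimate, list(posteriors))
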