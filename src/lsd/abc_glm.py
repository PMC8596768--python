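"""ABC reference tables, PLS reduction and GLM posterior densities on a grid.

The inference backbone of the scan: a reference table of single-locus
coalescent simulations with parameters drawn from the priors; a supervised
(partial least squares) reduction of the standardized summary statistics to a
few parameter-informative components; retention of the simulations closest to
the observed statistics in that space; an ordinary-least-squares
linear-Gaussian model ``s = c0 + B theta + eps`` fitted to the retained rows;
and the resulting posterior density of the focal parameters
``(log10 M12, log10 M21)`` evaluated on a regular grid over the prior box
(uniform prior on the log10 scale). All density arithmetic is in log space
with a floor of 1e-300 before normalization.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cross_decomposition import PLSRegression

from .coalescent import _as_rng, simulate_locus
from .demography import (
    DemographicModel,
    ParameterPrior,
    ResolvedDemography,
    sample_parameters,
)
from .sumstats import stats_vector

DENSITY_FLOOR = 1e-300
DEFAULT_RETENTION_FRACTION = 0.01
RETENTION_FLOOR = 1000


def retention_size(n_sims: int, fraction: float = DEFAULT_RETENTION_FRACTION,
                   floor: int = RETENTION_FLOOR) -> int:
    """Number of closest simulations to retain: ``max(floor, fraction*n)``, capped at n."""
    return min(n_sims, max(floor, int(round(fraction * n_sims))))


def _param_column(prior: ParameterPrior) -> str:
    return f"log10_{prior.name}" if prior.scale == "log10" else prior.name


def _model_hash(model: DemographicModel) -> str:
    text = repr(model).encode()
    return hashlib.sha256(text).hexdigest()[:12]


@dataclass
class ReferenceTable:
    """Rows of (parameters on their prior scale, summary statistics).

    ``params`` columns are named ``log10_<name>`` for log10-scale priors.
    ``ok`` flags rows with fully defined statistics; only those participate
    in transforms and retention.
    """

    params: pd.DataFrame
    stats: pd.DataFrame
    priors: list
    focal: list  #: focal parameter names (natural names, e.g. ["M12", "M21"])
    metadata: dict = field(default_factory=dict)

    @property
    def ok(self) -> np.ndarray:
        return ~self.stats.isna().any(axis=1).to_numpy()

    @property
    def focal_columns(self) -> list[str]:
        by_name = {p.name: p for p in self.priors}
        return [_param_column(by_name[f]) for f in self.focal]

    def prior_bounds(self, name: str) -> tuple[float, float]:
        p = next(p for p in self.priors if p.name == name)
        return p.lower, p.upper

    # --- persistence (TSV with a '#'-prefixed JSON header block) -----------
    def to_tsv(self, path) -> None:
        header = {
            "priors": [[p.name, p.scale, p.lower, p.upper] for p in self.priors],
            "focal": self.focal,
            **self.metadata,
        }
        with open(path, "w") as fh:
            fh.write("# lsd reference table\n")
            fh.write("# " + json.dumps(header) + "\n")
            pd.concat([self.params, self.stats], axis=1).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            fh.readline()
            header = json.loads(fh.readline().lstrip("# ").strip())
            df = pd.read_csv(fh, sep="\t")
        priors = [ParameterPrior(*row) for row in header.pop("priors")]
        focal = header.pop("focal")
        n_par = len(priors)
        return cls(df.iloc[:, :n_par], df.iloc[:, n_par:], priors, focal, header)


def build_reference_table(
    model: DemographicModel,
    priors: Sequence[ParameterPrior],
    n_sims: int,
    sample_config: Mapping[str, int],
    locus_length: int,
    rng,
    *,
    focal: Sequence[str] = ("M12", "M21"),
    sfs_bins: int = 0,
    seed_label=None,
) -> ReferenceTable:
    """Simulate ``n_sims`` independent single-locus draws from the priors.

    Each row pairs the drawn parameters (stored on the prior scale) with the
    locus's summary-statistics vector. Aborts if more than half the rows have
    undefined statistics.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = _as_rng(rng)
    pops = list(sample_config)
    param_rows = np.empty((n_sims, len(priors)))
    stat_rows = []
    for i in range(n_sims):
        params = sample_parameters(priors, rng)
        for j, p in enumerate(priors):
            v = params[p.name]
            param_rows[i, j] = np.log10(v) if p.scale == "log10" else v
        locus = simulate_locus(model, params, sample_config, locus_length, rng)
        stat_rows.append(stats_vector(locus, pops, sfs_bins=sfs_bins).to_numpy())
    from .sumstats import stat_names

    stats = pd.DataFrame(np.vstack(stat_rows), columns=stat_names(pops, sfs_bins))
    params_df = pd.DataFrame(param_rows, columns=[_param_column(p) for p in priors])
    table = ReferenceTable(
        params_df,
        stats,
        list(priors),
        [f for f in focal],
        {"model_hash": _model_hash(model), "seed": seed_label, "locus_length": locus_length,
         "sample_config": {str(k): int(v) for k, v in sample_config.items()}},
    )
    frac_bad = 1.0 - table.ok.mean()
    if frac_bad > 0.5:
        raise RuntimeError(
            f"{frac_bad:.0%} of reference rows have undefined statistics; "
            "check the model, sample sizes or statistic choice"
        )
    return table


#: statistics with heavy right tails (counts and count-like diversities) enter
#: the transform on a log1p scale; bounded statistics stay linear.
LOG_SCALE_PREFIXES = ("S_", "privS_", "pi_", "thetaW_", "dxy_")


def _log_scaled(name: str) -> bool:
    return name.startswith(LOG_SCALE_PREFIXES)


@dataclass
class StatTransform:
    """log1p pre-scaling (count-like statistics), standardization and PLS.

    Under the wide log-uniform migration priors the count-like statistics
    span several orders of magnitude; without the fixed log1p pre-scaling the
    linear projection is dominated by the low-migration tail.
    """

    names: list  #: statistics kept (non-constant, ordered)
    log_mask: np.ndarray  #: which statistics are log1p-scaled
    mean: np.ndarray
    sd: np.ndarray
    pls: PLSRegression | None  #: None = no reduction (standardized pass-through)
    n_components: int

    def transform(self, stats) -> np.ndarray:
        """Project statistics (Series, DataFrame or array) to PLS scores."""
        if isinstance(stats, pd.Series):
            x = stats[self.names].to_numpy(dtype=float)[None, :]
        elif isinstance(stats, pd.DataFrame):
            x = stats[self.names].to_numpy(dtype=float)
        else:
            x = np.atleast_2d(np.asarray(stats, dtype=float))
        if np.isnan(x).any():
            bad = [self.names[j] for j in np.unique(np.where(np.isnan(x))[1])]
            raise ValueError(f"missing statistic(s): {bad}")
        x = x.copy()
        x[:, self.log_mask] = np.log1p(np.maximum(x[:, self.log_mask], 0.0))
        z = (x - self.mean) / self.sd
        return z if self.pls is None else self.pls.transform(z)


def fit_transform(table: ReferenceTable, k: int) -> StatTransform:
    """Fit the k-component PLS of focal parameters on scaled statistics.

    Constant statistics are dropped with a warning; collinear duplicates are
    tolerated by PLS.
    """
    if k < 1:
        raise ValueError("need at least one PLS component")
    ok = table.ok
    x_all = table.stats.loc[ok].to_numpy(dtype=float)
    all_names = list(table.stats.columns)
    log_mask_all = np.array([_log_scaled(n) for n in all_names])
    x_all = x_all.copy()
    x_all[:, log_mask_all] = np.log1p(np.maximum(x_all[:, log_mask_all], 0.0))
    sd_all = x_all.std(axis=0, ddof=1)
    keep = sd_all > 0
    dropped = [n for n, k_ in zip(all_names, keep) if not k_]
    if dropped:
        warnings.warn(f"dropping constant statistic(s): {dropped}", stacklevel=2)
    names = [n for n, k_ in zip(all_names, keep) if k_]
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} usable statistics")
    x = x_all[:, keep]
    mean = x.mean(axis=0)
    sdv = sd_all[keep]
    y = table.params.loc[ok, table.focal_columns].to_numpy()
    pls = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on near-null deflation
        pls.fit((x - mean) / sdv, y)
    return StatTransform(names, log_mask_all[keep], mean, sdv, pls, k)


def _table_scores(table: ReferenceTable, transform: StatTransform) -> np.ndarray:
    """PLS scores of the table's usable rows, cached per (table, transform)."""
    cache = getattr(table, "_score_cache", None)
    key = id(transform)
    if cache is None or cache[0] is not key:
        scores = transform.transform(table.stats.loc[table.ok])
        table._score_cache = (key, scores)
    return table._score_cache[1]


def retain_closest(
    table: ReferenceTable, transform: StatTransform, s_obs, n_ret: int
) -> pd.Index:
    """Indices of the ``n_ret`` rows closest to ``s_obs`` in PLS space.

    Euclidean distance; ties at the cutoff break by row index (stable sort).
    """
    ok = table.ok
    if n_ret > int(ok.sum()):
        raise ValueError(f"n_ret={n_ret} exceeds the {int(ok.sum())} usable rows")
    scores = _table_scores(table, transform)
    target = transform.transform(s_obs)
    d2 = np.sum((scores - target) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")[:n_ret]
    return table.stats.index[ok][order]


@dataclass
class GLMFit:
    """Linear-Gaussian likelihood model s = c0 + B theta + eps, eps ~ N(0, Sigma)."""

    c0: np.ndarray  #: (k,)
    B: np.ndarray  #: (k, p) statistic-by-parameter coefficients
    sigma: np.ndarray  #: (k, k) ridge-regularized residual covariance
    param_names: list


def fit_glm(theta: np.ndarray, scores: np.ndarray, param_names: Sequence[str]) -> GLMFit:
    """OLS of PLS scores on focal parameters over the retained rows.

    ``Sigma`` is the residual covariance plus a ridge ``delta * I`` with
    ``delta = 1e-8 * mean diagonal`` so it is always positive definite.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n, p = theta.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit the GLM, got {n}")
    design = np.column_stack([np.ones(n), theta])
    coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    resid = scores - design @ coef
    sigma = resid.T @ resid / max(n - (p + 1), 1)
    scale = np.trace(sigma) / sigma.shape[0]
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    sigma = sigma + 1e-8 * scale * np.eye(sigma.shape[0])
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise RuntimeError("residual covariance is rank deficient even after ridge")
    return GLMFit(coef[0], coef[1:].T, sigma, list(param_names))


@dataclass
class PosteriorGrid:
    """Normalized posterior mass over a regular (log10 M12, log10 M21) grid."""

    axis_names: list  #: e.g. ["log10_M12", "log10_M21"]
    axes: list  #: list of 1-D center arrays, mass.shape == tuple(map(len, axes))
    mass: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.mass.sum())
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"mass must sum to 1 (got {total})")
        if (self.mass < 0).any():
            raise ValueError("negative posterior mass")

    @property
    def shape(self) -> tuple:
        return self.mass.shape

    def mode(self) -> tuple:
        """Grid indices of the maximum-mass cell (first occurrence on ties)."""
        return tuple(int(i) for i in np.unravel_index(int(np.argmax(self.mass)), self.shape))

    def cell_values(self, idx: tuple) -> tuple:
        return tuple(float(self.axes[d][i]) for d, i in enumerate(idx))

    def entropy(self) -> float:
        m = np.clip(self.mass, DENSITY_FLOOR, None)
        return float(-(m * np.log(m)).sum())

    def same_grid(self, other: "PosteriorGrid") -> bool:
        return self.axis_names == other.axis_names and all(
            np.array_equal(a, b) for a, b in zip(self.axes, other.axes)
        )


def grid_axes(
    priors: Sequence[ParameterPrior], focal: Sequence[str], shape: tuple = (33, 33)
) -> tuple[list, list]:
    """Cell-center axes over the prior box of the focal parameters."""
    by_name = {p.name: p for p in priors}
    names, axes = [], []
    for f, n_cells in zip(focal, shape):
        p = by_name[f]
        edges = np.linspace(p.lower, p.upper, n_cells + 1)
        axes.append(0.5 * (edges[:-1] + edges[1:]))
        names.append(_param_column(p))
    return names, axes


def posterior_grid(
    glm: GLMFit,
    priors: Sequence[ParameterPrior],
    transform: StatTransform,
    s_obs,
    *,
    focal: Sequence[str] = ("M12", "M21"),
    shape: tuple = (33, 33),
) -> PosteriorGrid:
    """Evaluate the ABC-GLM posterior of the focal parameters on a grid.

    Cell mass is proportional to ``prior(theta) * N(s_obs; c0 + B theta,
    Sigma)`` at the cell centers; the prior is uniform on the grid scale, so
    it contributes a constant. Underflow cannot zero the output: the
    normalization happens in log space.
    """
    names, axes = grid_axes(priors, focal, shape)
    target = transform.transform(s_obs)[0]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.column_stack([m.ravel() for m in mesh])
    mean = glm.c0 + theta @ glm.B.T
    diff = target - mean
    chol = np.linalg.cholesky(glm.sigma)
    sol = np.linalg.solve(chol, diff.T).T
    logdens = -0.5 * np.sum(sol**2, axis=1)
    logdens -= logsumexp(logdens)
    mass = np.exp(logdens)
    mass = np.clip(mass, DENSITY_FLOOR, None)
    mass /= mass.sum()
    return PosteriorGrid(names, axes, mass.reshape([len(a) for a in axes]))


def truncation_log_weight(theta: np.ndarray, grid_points: np.ndarray) -> np.ndarray:
    """Log density of the truncated prior carried by the retained simulations.

    The GLM likelihood is only trustworthy where simulations were actually
    retained; following the truncated-prior construction of the GLM
    algorithm, the retained parameter draws are smoothed with a Gaussian
    product kernel (Scott's bandwidth) and evaluated at the grid centers.
    Without this factor the linear-Gaussian extrapolation can place spurious
    mass in parameter regions no retained simulation supports.
    """
    n, d = theta.shape
    bw = theta.std(axis=0, ddof=1) * n ** (-1.0 / (d + 4))
    bw = np.where(bw > 0, bw, 1.0)
    z = (grid_points[:, None, :] - theta[None, :, :]) / bw
    return logsumexp(-0.5 * np.sum(z * z, axis=2), axis=1)


def locus_posterior(
    table: ReferenceTable,
    transform: StatTransform,
    s_obs,
    *,
    n_retain: int | None = None,
    shape: tuple = (33, 33),
    truncate: bool = True,
) -> PosteriorGrid:
    """Retention + truncated prior + GLM fit + grid evaluation for one locus."""
    if n_retain is None:
        n_retain = retention_size(len(table.params))
    idx = retain_closest(table, transform, s_obs, n_retain)
    theta = table.params.loc[idx, table.focal_columns].to_numpy()
    scores = transform.transform(table.stats.loc[idx])
    glm = fit_glm(theta, scores, table.focal_columns)
    grid = posterior_grid(glm, table.priors, transform, s_obs, focal=table.focal, shape=shape)
    if not truncate:
        return grid
    mesh = np.meshgrid(*grid.axes, indexing="ij")
    points = np.column_stack([m.ravel() for m in mesh])
    logmass = np.log(np.clip(grid.mass.ravel(), DENSITY_FLOOR, None))
    logmass = logmass + truncation_log_weight(theta, points)
    logmass -= logsumexp(logmass)
    mass = np.clip(np.exp(logmass), DENSITY_FLOOR, None)
    mass /= mass.sum()
    return PosteriorGrid(grid.axis_names, grid.axes, mass.reshape(grid.shape))
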