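"""Power evaluation: ROC curves, Mann-Whitney AUC, and robustness experiments.

Loci are scored by ``1 - p_l`` (a low HPD p-value marks an outlier), and the
scan's ability to separate selected from neutral loci is summarized as the
area under the ROC curve, computed as the Mann-Whitney U statistic with
midrank tie handling (equal to the trapezoidal area under the empirical ROC
staircase). The neutral-set mis-specification experiment re-estimates the
neutral point from a contaminated subset and measures the change in AUC; the
regime grid sweeps migration-selection regimes, reporting loss regimes (where
the derived allele is always lost) explicitly rather than skipping them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .abc_glm import ReferenceTable, StatTransform
from .coalescent import _as_rng
from .scan import ScanResult, asymmetry_score, run_scan
from .selection import LossRegimeError, Pseudogenome, SelectionRegime, build_pseudogenome
from .sumstats import stats_vector


@dataclass
class LabeledScores:
    """Per-locus scores in [0, 1] with true labels ("neutral"/"selected")."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must align")

    @classmethod
    def from_scan(cls, result: ScanResult, labels: Sequence) -> "LabeledScores":
        return cls(1.0 - result.records["p"].to_numpy(), np.asarray(labels))

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.scores[self.labels == "selected"]
        neu = self.scores[self.labels == "neutral"]
        if len(sel) == 0 or len(neu) == 0:
            raise ValueError("both classes must be non-empty")
        return sel, neu


def roc_curve(scores: LabeledScores) -> np.ndarray:
    """Ordered (FPR, TPR) staircase over all distinct score thresholds."""
    sel, neu = scores.split()
    thresholds = np.unique(np.concatenate([scores.scores, [0.0, 1.0]]))[::-1]
    pts = [
        (float(np.mean(neu >= t)), float(np.mean(sel >= t))) for t in thresholds
    ]
    pts = [(0.0, 0.0)] + pts + [(1.0, 1.0)]
    arr = np.unique(np.asarray(pts), axis=0)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def auc(scores: LabeledScores) -> float:
    """Mann-Whitney AUC with midrank ties: P(selected outranks neutral)."""
    sel, neu = scores.split()
    ranks = rankdata(np.concatenate([sel, neu]))
    u = ranks[: len(sel)].sum() - len(sel) * (len(sel) + 1) / 2.0
    return float(u / (len(sel) * len(neu)))


def trapezoid_auc(scores: LabeledScores) -> float:
    """Trapezoidal area under :func:`roc_curve` (equals :func:`auc`)."""
    curve = roc_curve(scores)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def pseudogenome_stats(genome: Pseudogenome, pops: Sequence, *, sfs_bins: int = 0) -> pd.DataFrame:
    """Per-locus statistics table (index = locus index) for a pseudogenome."""
    rows = [stats_vector(locus, pops, sfs_bins=sfs_bins) for locus, _, _ in genome.loci]
    df = pd.DataFrame(rows).reset_index(drop=True)
    df.index.name = "locus_id"
    return df


def scan_pseudogenome(
    genome: Pseudogenome,
    table: ReferenceTable,
    transform: StatTransform,
    *,
    neutral_ids: Sequence | None = None,
    n_retain: int | None = None,
    grid_shape: tuple = (33, 33),
    posteriors=None,
) -> tuple[ScanResult, LabeledScores]:
    """Scan a labelled pseudogenome; the truth labels ride along for scoring.

    By default the designated neutral subset is the truly neutral loci (the
    validation design's idealized case). The statistics are computed with the
    SFS binning the transform was fitted with.
    """
    from .sumstats import infer_sfs_bins

    pops = list(dict.fromkeys(genome.loci[0][0].pop_labels))
    stats = pseudogenome_stats(genome, pops, sfs_bins=infer_sfs_bins(transform.names))
    labels = np.asarray(genome.labels)
    if neutral_ids is None:
        neutral_ids = list(np.flatnonzero(labels == "neutral"))
    result = run_scan(
        stats,
        table,
        transform,
        neutral_ids=neutral_ids,
        n_retain=n_retain,
        grid_shape=grid_shape,
        posteriors=posteriors,
    )
    return result, LabeledScores.from_scan(result, labels)


def misspecification_experiment(
    genome: Pseudogenome,
    contamination: float,
    table: ReferenceTable,
    transform: StatTransform,
    rng,
    *,
    n_retain: int | None = None,
    grid_shape: tuple = (33, 33),
    posteriors=None,
) -> float:
    """AUC when a fraction of the designated neutral set is in fact selected.

    The neutral subset keeps its size: ``floor(f * n)`` of its members are
    replaced by selected loci drawn without replacement. ``f = 0``
    reproduces the clean scan exactly.
    """
    if not 0.0 <= contamination <= 0.5:
        raise ValueError("contamination fraction must lie in [0, 0.5]")
    rng = _as_rng(rng)
    labels = np.asarray(genome.labels)
    neutral = np.flatnonzero(labels == "neutral")
    selected = np.flatnonzero(labels == "selected")
    n_swap = int(np.floor(contamination * len(neutral)))
    if n_swap > len(selected):
        raise ValueError(
            f"cannot contaminate with {n_swap} selected loci; only {len(selected)} exist"
        )
    drop = rng.choice(neutral, size=n_swap, replace=False) if n_swap else np.empty(0, int)
    add = rng.choice(selected, size=n_swap, replace=False) if n_swap else np.empty(0, int)
    subset = sorted(set(neutral) - set(drop.tolist()) | set(add.tolist()))
    result, scores = scan_pseudogenome(
        genome,
        table,
        transform,
        neutral_ids=subset,
        n_retain=n_retain,
        grid_shape=grid_shape,
        posteriors=posteriors,
    )
    return auc(scores)


def regime_grid(
    model,
    params_base: Mapping[str, float],
    regimes: Sequence[Mapping],
    table: ReferenceTable,
    transform: StatTransform,
    sample_config: Mapping[str, int],
    rng,
    *,
    n_neutral: int = 200,
    n_selected: int = 50,
    locus_length: int = 5000,
    n_retain: int | None = None,
    grid_shape: tuple = (33, 33),
    resample_cap: int = 10_000,
    rescale_cap: float = 1000.0,
) -> pd.DataFrame:
    """One pseudogenome + scan per regime; tidy table of (regime, AUC, a).

    Each regime mapping carries ``M`` (the symmetric neutral migration rate),
    ``s1``, ``s2`` and ``t_onset`` plus optional SelectionRegime fields. Loss
    regimes are reported with ``loss_regime=True`` and NaN metrics, never
    silently skipped.
    """
    if not regimes:
        raise ValueError("no regimes given")
    rng = _as_rng(rng)
    rows = []
    for spec in regimes:
        spec = dict(spec)
        m = spec.pop("M")
        regime = SelectionRegime(
            s1=spec.pop("s1"),
            s2=spec.pop("s2"),
            t_onset=spec.pop("t_onset"),
            **spec,
        )
        params = dict(params_base)
        params["M12"] = params["M21"] = m
        row = {"M": m, "s1": regime.s1, "s2": regime.s2, "t_onset": regime.t_onset}
        try:
            genome = build_pseudogenome(
                model,
                params,
                regime,
                n_neutral,
                n_selected,
                locus_length,
                sample_config,
                rng,
                resample_cap=resample_cap,
                rescale_cap=rescale_cap,
            )
        except LossRegimeError:
            rows.append({**row, "loss_regime": True, "auc": np.nan, "a": np.nan})
            continue
        result, scores = scan_pseudogenome(
            genome, table, transform, n_retain=n_retain, grid_shape=grid_shape
        )
        sel_sigma = result.records.loc[
            np.asarray(genome.labels) == "selected", "sigma"
        ].to_numpy()
        rows.append(
            {
                **row,
                "loss_regime": False,
                "auc": auc(scores),
                "a": asymmetry_score(sel_sigma, mode="aggregate_selected"),
            }
        )
    return pd.DataFrame(rows)
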