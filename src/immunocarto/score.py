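"""Module scores, activation thresholds, and dominance calling.

A raw module score is the mean log2 normalized expression of the
module's genes in one sample.  For each module a threshold is fitted as
the local density minimum between the two modes of the pooled sentinel
score distribution (module-positive vs module-negative sentinels); raw
scores are then mapped through a logistic to a [0, 1] activation score
anchored at 0.5 exactly at the threshold and reaching 0.01 / 0.99 at
the nearer of the sentinel score minimum / maximum.

A module is called *dominant* in a sample when its activation exceeds
0.5 and its raw score is significantly greater than every other
module's (one-sided gene-resampling bootstrap within the sample).  When
no module dominates but several exceed 0.5 within 30% of the highest,
they are called *co-dominant*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .discover import ModuleSet
from .exceptions import ConfigurationError, DataError, StatisticsError
from .normalize import NormalizedMatrix


def module_score(
    norm: NormalizedMatrix | pd.DataFrame, modules: ModuleSet
) -> pd.DataFrame:
    """samples × modules matrix of mean log2 expression of module genes."""
    data = norm.data if isinstance(norm, NormalizedMatrix) else norm
    for name, genes in modules.modules.items():
        if not genes:
            raise DataError(f"module {name!r} is empty")
    modules.validate_against(data)
    return pd.DataFrame(
        {name: data[genes].mean(axis=1) for name, genes in modules.modules.items()},
        index=data.index,
    )


def fit_threshold(
    scores: pd.Series | np.ndarray,
    is_positive: pd.Series | np.ndarray,
    bw_method: str | float = "silverman",
    grid_size: int = 512,
) -> float:
    """Bimodal-valley threshold between module-negative and -positive scores.

    The pooled scores are smoothed with a Gaussian KDE; the threshold is
    the density minimum strictly between the two highest modes (ties in
    mode height broken toward the lower-score mode).  If the density is
    unimodal, or the valley falls outside the open interval between the
    negative- and positive-group means, the midpoint of the two group
    means is used instead.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos, n_neg = int(is_positive.sum()), int((~is_positive).sum())
    if n_pos < 3 or n_neg < 3:
        raise StatisticsError(
            f"need >= 3 positive and >= 3 negative sentinels, got {n_pos}/{n_neg}"
        )
    neg_mean = float(scores[~is_positive].mean())
    pos_mean = float(scores[is_positive].mean())
    midpoint = 0.5 * (neg_mean + pos_mean)
    if np.ptp(scores) == 0:
        return midpoint

    try:
        kde = gaussian_kde(scores, bw_method=bw_method)
    except np.linalg.LinAlgError:
        return midpoint
    grid = np.linspace(scores.min(), scores.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    modes = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        modes = np.r_[0, modes]
    if dens[-1] > dens[-2]:
        modes = np.r_[modes, grid_size - 1]
    if len(modes) < 2:
        return midpoint
    # two highest modes; ties broken toward the lower-score mode
    order = sorted(modes, key=lambda i: (-dens[i], grid[i]))
    lo, hi = sorted(order[:2])
    if hi - lo < 2:
        return midpoint
    valley = lo + 1 + int(np.argmin(dens[lo + 1 : hi]))
    t = float(grid[valley])
    low, high = sorted((neg_mean, pos_mean))
    if not low < t < high:
        return midpoint
    return t


def activation(
    x: float | np.ndarray | pd.Series, t: float, lo: float, hi: float
) -> float | np.ndarray | pd.Series:
    """Logistic activation in [0, 1], = 0.5 exactly at the threshold.

    The steepness k = ln(99) / min(t − lo, hi − t) makes the activation
    reach 0.01 or 0.99 at the nearer of the sentinel score extremes;
    strictly increasing in x.
    """
    if not lo < t < hi:
        raise StatisticsError(
            f"threshold {t} not strictly inside sentinel range ({lo}, {hi})"
        )
    k = np.log(99.0) / min(t - lo, hi - t)
    if np.isscalar(x):
        return float(expit(k * (x - t)))
    if isinstance(x, pd.Series):
        return pd.Series(expit(k * (x.to_numpy(dtype=float) - t)), index=x.index)
    return expit(k * (np.asarray(x, dtype=float) - t))


@dataclass
class ModuleScoreTable:
    """Fitted per-module score model over a sentinel cohort."""

    scores: pd.DataFrame        # sentinel samples × modules, raw scores
    thresholds: pd.Series       # module -> t_m
    score_min: pd.Series        # module -> sentinel min
    score_max: pd.Series        # module -> sentinel max
    steepness: pd.Series        # module -> k_m > 0
    gene_reference: pd.Series | None = None  # gene -> sentinel mean log2

    def activation_of(self, scores: pd.DataFrame) -> pd.DataFrame:
        """Map raw scores (any cohort) to [0, 1] activations."""
        out = {}
        for m in self.thresholds.index:
            out[m] = expit(
                self.steepness[m] * (scores[m].to_numpy(dtype=float) - self.thresholds[m])
            )
        return pd.DataFrame(out, index=scores.index)


def fit_score_table(
    norm: NormalizedMatrix | pd.DataFrame,
    modules: ModuleSet,
    sample_disease: pd.Series,
    disease_positive: Mapping[str, tuple[str, ...]],
    bw_method: str | float = "silverman",
) -> ModuleScoreTable:
    """Fit thresholds and logistic steepness on a sentinel cohort.

    ``disease_positive`` maps a disease to the modules it activates at
    dominant level; sentinels of such diseases are the module-positive
    group for threshold fitting, all other sentinels the negative group.
    Per-gene sentinel means are stored as the reference for the
    dominance bootstrap.
    """
    data = norm.data if isinstance(norm, NormalizedMatrix) else norm
    scores = module_score(data, modules)
    gene_reference = data[modules.all_genes].mean(axis=0)
    sample_disease = sample_disease.reindex(scores.index)
    thresholds, k_vals, mins, maxs = {}, {}, {}, {}
    for m in scores.columns:
        pos_diseases = {d for d, mods in disease_positive.items() if m in mods}
        is_pos = sample_disease.isin(pos_diseases).to_numpy()
        t = fit_threshold(scores[m], is_pos, bw_method=bw_method)
        lo, hi = float(scores[m].min()), float(scores[m].max())
        if not lo < t < hi:
            raise StatisticsError(
                f"module {m!r}: fitted threshold {t:.3f} outside sentinel score range"
            )
        thresholds[m] = t
        mins[m], maxs[m] = lo, hi
        k_vals[m] = float(np.log(99.0) / min(t - lo, hi - t))
    return ModuleScoreTable(
        scores=scores,
        thresholds=pd.Series(thresholds),
        score_min=pd.Series(mins),
        score_max=pd.Series(maxs),
        steepness=pd.Series(k_vals),
        gene_reference=gene_reference,
    )


@dataclass
class DominanceCall:
    """Per-sample dominance status."""

    status: str                          # "dominant" | "co-dominant" | "none"
    dominant: str | None
    codominant: tuple[str, ...]
    bootstrap_p: dict[str, float]        # other module -> one-sided p


def call_codominance(activations: pd.Series, fraction: float = 0.7) -> tuple[str, ...]:
    """Modules with activation > 0.5 within 30% of the highest activation."""
    a = activations.astype(float)
    top = a.max()
    keep = a.index[(a > 0.5) & (a >= fraction * top)]
    return tuple(keep)


def call_dominance(
    activations: pd.Series,
    gene_values: Mapping[str, np.ndarray],
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    codominance_fraction: float = 0.7,
) -> DominanceCall:
    """Dominance call for one sample.

    ``gene_values`` maps each module to the sample's log2 expression of
    that module's genes, usually centered on a per-gene reference level
    (the sentinel cohort mean) so that score comparisons across modules
    are not confounded by fixed baseline differences between genes.  A
    candidate module (activation > 0.5) is dominant when, against every
    other module, the one-sided bootstrap p for its score excess
    (module genes resampled with replacement, ``n_boot`` replicates) is
    below ``alpha``.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    rng = np.random.default_rng(rng)
    mods = list(activations.index)
    raw = {m: float(np.mean(gene_values[m])) for m in mods}
    # bootstrap score distribution per module (modules are disjoint →
    # independent resampling)
    boot = {}
    for m in mods:
        vals = np.asarray(gene_values[m], dtype=float)
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boot[m] = vals[idx].mean(axis=1)

    over = [m for m in mods if activations[m] > 0.5]
    pvals: dict[str, float] = {}
    for m in sorted(over, key=lambda m: -raw[m]):
        ps = {
            o: float(np.mean(boot[m] - boot[o] <= 0.0)) for o in mods if o != m
        }
        if all(p < alpha for p in ps.values()):
            return DominanceCall("dominant", m, (), ps)
        pvals = ps
        break  # only the top-scoring candidate can beat all others
    if len(over) >= 2:
        co = call_codominance(activations, codominance_fraction)
        if len(co) >= 2:
            return DominanceCall("co-dominant", None, co, pvals)
    return DominanceCall("none", None, (), pvals)


@dataclass
class ActivationTable:
    """Per-sample activations and dominance calls for a cohort."""

    activations: pd.DataFrame
    calls: dict[str, DominanceCall]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.activations.index:
            c = self.calls[sid]
            rows.append(
                {
                    "status": c.status,
                    "dominant": c.dominant or "",
                    "codominant": "+".join(c.codominant),
                }
            )
        return pd.concat(
            [self.activations, pd.DataFrame(rows, index=self.activations.index)], axis=1
        )


def score_and_call(
    norm: NormalizedMatrix | pd.DataFrame,
    modules: ModuleSet,
    table: ModuleScoreTable,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> ActivationTable:
    """Score a cohort against a fitted table and call dominance per sample.

    The dominance bootstrap runs on reference-centered gene values
    (sample expression minus the fitted sentinel per-gene mean), so a
    module is dominant when it is the most strongly *activated*, not
    merely the one whose genes sit on the highest baseline.
    """
    data = norm.data if isinstance(norm, NormalizedMatrix) else norm
    scores = module_score(data, modules)
    acts = table.activation_of(scores)
    ref = table.gene_reference
    rng = np.random.default_rng(seed)
    calls = {}
    for sid in data.index:
        gene_values = {}
        for m, genes in modules.modules.items():
            vals = data.loc[sid, genes].to_numpy(dtype=float)
            if ref is not None:
                vals = vals - ref[genes].to_numpy(dtype=float)
            gene_values[m] = vals
        calls[sid] = call_dominance(
            acts.loc[sid], gene_values, n_boot=n_boot, alpha=alpha, rng=rng
        )
    return ActivationTable(activations=acts, calls=calls)
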