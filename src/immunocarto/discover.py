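"""Immune-module discovery by one-vs-rest differential expression.

Each module is derived from a contrast between one sentinel disease
group and the remaining sentinels on the log2 normalized matrix.  Genes
pass with log2 fold change above a threshold and (BH-adjusted, by
default) p-value below a threshold, up-regulated side only.  Genes
passing several contrasts are assigned to the contrast with the largest
fold change, which keeps the module gene lists pairwise disjoint.

The default test is a moderated t-test: per-gene pooled variances are
shrunk toward a common prior fitted by empirical Bayes (scaled
inverse-chi-square, method of moments on log variances), and the t
statistic is referred to a t distribution with augmented degrees of
freedom.  A plain Welch t-test is available as a fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DataError, StatisticsError

#: The six model diseases used as reference ("sentinel") groups.
SENTINEL_DISEASES = ("PsO", "AD", "LP", "CLE", "NeuD", "Wells")


# ----------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ----------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward a fitted prior.

    Returns (posterior variances, prior df d0, prior variance s0^2);
    d0 = inf when the observed log-variance spread is no wider than the
    chi-square sampling spread (all variances squeezed to the prior).
    """
    ok = s2 > 0
    if not ok.any():
        return s2.copy(), np.inf, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        # log-variance spread no wider than chi-square sampling noise:
        # infinite prior df, all variances squeezed to their mean
        d0 = np.inf
        s02 = float(s2[ok].mean())
        post = np.full_like(s2, s02)
    return post, d0, s02


def differential_expression(
    norm: pd.DataFrame,
    labels: pd.Series,
    target_group: str,
    rest_groups: Sequence[str] | None = None,
    method: str = "moderated",
) -> pd.DataFrame:
    """One-vs-rest differential expression on a log2 matrix.

    Returns a per-gene table with columns ``log2fc`` (target mean − rest
    mean), ``pvalue`` (two-sided) and ``padj`` (Benjamini–Hochberg over
    all tested genes).
    """
    labels = labels.reindex(norm.index)
    target_idx = labels[labels == target_group].index
    if rest_groups is None:
        rest_idx = labels[(labels != target_group) & labels.notna()].index
    else:
        rest_idx = labels[labels.isin(rest_groups)].index
    n1, n2 = len(target_idx), len(rest_idx)
    if n1 < 2 or n2 < 2:
        raise StatisticsError(
            f"contrast {target_group!r}: need >= 2 samples per side, got {n1} vs {n2}"
        )
    a = norm.loc[target_idx].to_numpy(dtype=float)
    b = norm.loc[rest_idx].to_numpy(dtype=float)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    log2fc = m1 - m2

    if method == "welch":
        tstat, pvalue = stats.ttest_ind(a, b, equal_var=False)
        pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
    elif method == "moderated":
        df_resid = n1 + n2 - 2
        s2 = (a.var(axis=0, ddof=1) * (n1 - 1) + b.var(axis=0, ddof=1) * (n2 - 1)) / df_resid
        s2_post, d0, _ = squeeze_variances(s2, df_resid)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = log2fc / se
        # prior df augments the reference df, capped at the pooled df
        # available across all genes
        df_total = min(df_resid + d0, len(log2fc) * df_resid)
        pvalue = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        # degenerate genes: no variance anywhere on either side
        flat = se == 0
        pvalue[flat & (log2fc == 0)] = 1.0
        pvalue[flat & (log2fc != 0)] = 0.0
    else:
        raise ConfigurationError(f"unknown DE method {method!r}")

    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "padj": padj}, index=norm.columns
    )


def select_module_genes(
    de: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    use_adjusted: bool = True,
) -> list[str]:
    """Genes up-regulated beyond both thresholds (one-sided on FC)."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ConfigurationError("thresholds must be strictly positive")
    if de.empty:
        return []
    pcol = "padj" if use_adjusted else "pvalue"
    keep = (de["log2fc"] > fc_threshold) & (de[pcol] < p_threshold)
    return list(de.index[keep])


# ----------------------------------------------------------------------
# module set assembly
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """target group vs an explicit rest set (None → all other groups)."""

    module: str
    target: str
    rest: tuple[str, ...] | None = None


def default_contrasts(groups: Iterable[str]) -> list[Contrast]:
    """Standard one-vs-rest sentinel contrasts plus the myeloid split.

    The myeloid signature cannot be resolved by NeuD-vs-sentinels alone;
    neutrophilic, macrophagic and eosinophilic modules are split by
    contrasting NeuD, COVID-skin and Wells against each other when all
    three groups are present.
    """
    present = set(groups)
    sentinels = [g for g in SENTINEL_DISEASES if g in present]
    contrasts = []
    for module, target in (("Th17", "PsO"), ("Th2", "AD"), ("Th1", "LP"), ("IFN-I", "CLE")):
        if target in present:
            rest = tuple(g for g in sentinels if g != target)
            contrasts.append(Contrast(module, target, rest))
    myeloid_groups = ("NeuD", "COVID-skin", "Wells")
    if all(g in present for g in myeloid_groups):
        for module, target in (("neutro", "NeuD"), ("macro", "COVID-skin"), ("eosino", "Wells")):
            rest = tuple(g for g in myeloid_groups if g != target)
            contrasts.append(Contrast(module, target, rest))
    else:
        for module, target in (("neutro", "NeuD"), ("eosino", "Wells")):
            if target in present:
                rest = tuple(g for g in sentinels if g != target)
                contrasts.append(Contrast(module, target, rest))
    return contrasts


@dataclass
class ModuleSet:
    """Named, pairwise-disjoint gene lists plus provenance."""

    modules: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for mod, genes in self.modules.items():
            for g in genes:
                if g in seen:
                    raise DataError(
                        f"gene {g!r} appears in modules {seen[g]!r} and {mod!r}"
                    )
                seen[g] = mod

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, module: str) -> list[str]:
        return self.modules[module]

    @property
    def all_genes(self) -> list[str]:
        return [g for genes in self.modules.values() for g in genes]

    def validate_against(self, matrix: pd.DataFrame) -> None:
        missing = [g for g in self.all_genes if g not in matrix.columns]
        if missing:
            raise DataError(f"module genes absent from matrix: {missing[:10]}")

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"modules": self.modules, "provenance": self.provenance}, indent=2)
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "ModuleSet":
        obj = json.loads(Path(path).read_text())
        return cls(modules=obj["modules"], provenance=obj.get("provenance", {}))


def build_module_set(
    norm: pd.DataFrame,
    labels: pd.Series,
    contrasts: Sequence[Contrast] | None = None,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    use_adjusted: bool = True,
    exclusion_list: Iterable[str] = (),
    method: str = "moderated",
) -> ModuleSet:
    """Run all contrasts and assemble disjoint module gene lists.

    A gene passing several contrasts is assigned to the contrast with
    the largest log2 fold change; user-supplied exclusion-list genes are
    removed from every module.
    """
    if contrasts is None:
        contrasts = default_contrasts(labels.dropna().unique())
    present = set(labels.dropna().unique())
    for c in contrasts:
        for grp in (c.target, *(c.rest or ())):
            if grp not in present:
                raise ConfigurationError(
                    f"contrast for module {c.module!r} references unknown group {grp!r}"
                )
    exclusion = set(exclusion_list)
    best_fc: dict[str, float] = {}
    best_mod: dict[str, str] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    for c in contrasts:
        de = differential_expression(norm, labels, c.target, c.rest, method=method)
        de_tables[c.module] = de
        for g in select_module_genes(de, fc_threshold, p_threshold, use_adjusted):
            fc = float(de.loc[g, "log2fc"])
            if g not in best_fc or fc > best_fc[g]:
                best_fc[g] = fc
                best_mod[g] = c.module
    modules = {c.module: [] for c in contrasts}
    for g, mod in best_mod.items():
        if g not in exclusion:
            modules[mod].append(g)
    provenance = {
        "fc_threshold": fc_threshold,
        "p_threshold": p_threshold,
        "use_adjusted": use_adjusted,
        "method": method,
        "contrasts": {c.module: {"target": c.target, "rest": list(c.rest or ())} for c in contrasts},
        "excluded": sorted(exclusion),
    }
    return ModuleSet(modules=modules, provenance=provenance)
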