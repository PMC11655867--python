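"""nCounter-style two-step normalization.

Per-sample technical depth is estimated twice — first from the positive
control probes (assay efficiency), then from the housekeeping probes
(RNA content) — as the geometric mean of the relevant probe counts.
Each sample's counts are rescaled by a factor derived from its geometric
mean, the result is floored at 1 and log2-transformed.

Two factor directions are supported:

``corrective`` (default)
    factor_i = mean(geomeans) / geomean_i.  A sample whose controls run
    high is scaled *down*; scaling a sample's entire count vector by c
    leaves its normalized values unchanged (depth invariance).
``literal``
    factor_i = geomean_i / mean(geomeans), the mirror-image convention.
    It amplifies rather than removes depth differences and is provided
    for auditability only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .exceptions import DataError, NormalizationError

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")


@dataclass
class RawCounts:
    """Raw probe counts with probe annotation and sample metadata.

    counts      : samples × probes non-negative matrix
    annotation  : indexed by probe id; columns ``class`` (one of
                  :data:`PROBE_CLASSES`) and optionally ``true_module``
    metadata    : indexed by sample id; free-form columns (disease, role,
                  treatment, response, ...)
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataError("duplicate sample ids in counts matrix")
        if self.counts.columns.has_duplicates:
            raise DataError("duplicate probe ids in counts matrix")
        if self.counts.isna().any().any():
            raise DataError("missing values in counts matrix are illegal")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative counts are illegal")
        missing = self.counts.columns.difference(self.annotation.index)
        if len(missing):
            raise DataError(f"probes missing from annotation: {list(missing)[:5]}")
        bad = set(self.annotation["class"]) - set(PROBE_CLASSES)
        if bad:
            raise DataError(f"unknown probe classes: {sorted(bad)}")
        for cls in ("positive", "housekeeping"):
            if not (self.annotation["class"] == cls).any():
                raise DataError(f"no {cls} probes in annotation")

    def probes_of_class(self, cls: str) -> pd.Index:
        return self.annotation.index[self.annotation["class"] == cls].intersection(
            self.counts.columns, sort=False
        )

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index


@dataclass
class NormalizedMatrix:
    """log2 expression of endogenous probes plus the factors applied."""

    data: pd.DataFrame  # samples × endogenous probes, all values >= 0
    positive_factors: pd.Series
    housekeeping_factors: pd.Series
    direction: str = "corrective"

    def __post_init__(self) -> None:
        for name, fac in (
            ("positive", self.positive_factors),
            ("housekeeping", self.housekeeping_factors),
        ):
            if (fac <= 0).any():
                raise NormalizationError(f"non-positive {name} factors")


def _control_factor(
    matrix: pd.DataFrame, probes: pd.Index, direction: str, kind: str
) -> pd.Series:
    if len(probes) == 0:
        raise NormalizationError(f"no {kind} probes available")
    sub = matrix[probes]
    zero_rows = (sub <= 0).any(axis=1)
    if zero_rows.any():
        bad = sub.index[zero_rows][0]
        raise NormalizationError(
            f"sample {bad!r} has zero {kind} probe counts; geometric mean undefined"
        )
    geo = pd.Series(gmean(sub, axis=1), index=sub.index)
    grand = geo.mean()
    if direction == "corrective":
        return grand / geo
    if direction == "literal":
        return geo / grand
    raise NormalizationError(f"unknown direction {direction!r}")


def positive_control_factor(
    raw: RawCounts, direction: str = "corrective"
) -> pd.Series:
    """Per-sample factor from the positive-control probe geometric means."""
    return _control_factor(
        raw.counts, raw.probes_of_class("positive"), direction, "positive-control"
    )


def housekeeping_factor(
    intermediate: pd.DataFrame,
    annotation: pd.DataFrame,
    direction: str = "corrective",
) -> pd.Series:
    """Per-sample factor from housekeeping probes of the intermediate matrix."""
    probes = annotation.index[annotation["class"] == "housekeeping"].intersection(
        intermediate.columns, sort=False
    )
    return _control_factor(intermediate, probes, direction, "housekeeping")


def floor_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Floor values at 1, then log2: exact zeros for every input < 1."""
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise DataError("NaN values in matrix passed to floor_log2")
    return pd.DataFrame(
        np.log2(np.maximum(arr, 1.0)), index=matrix.index, columns=matrix.columns
    )


def normalize_counts(raw: RawCounts, direction: str = "corrective") -> NormalizedMatrix:
    """Full two-step normalization to log2 endogenous expression.

    positive-control factor → rescale → housekeeping factor → rescale →
    floor at 1 → log2, restricted to endogenous probes.
    """
    pos_f = positive_control_factor(raw, direction)
    intermediate = raw.counts.mul(pos_f, axis=0)
    hk_f = housekeeping_factor(intermediate, raw.annotation, direction)
    final = intermediate.mul(hk_f, axis=0)
    endo = raw.probes_of_class("endogenous")
    return NormalizedMatrix(
        data=floor_log2(final[endo]),
        positive_factors=pos_f,
        housekeeping_factors=hk_f,
        direction=direction,
    )
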