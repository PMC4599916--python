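"""Per-image intensity normalization.

Confocal fields differ in illumination and staining efficiency, so per-cell
intensities are only comparable across images after rescaling. Each image
mean is computed over all cellular-object observations it contributes; the
global reference is the observation-count-weighted average of image means
(identical to the grand per-cell mean). Every observation of image *i* is
multiplied by ``factor_i = global_mean / image_mean_i``, which makes all
image means equal to the global mean and conserves the grand mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError, NormalizationError

__all__ = [
    "NormalizationFactor",
    "IntensityNormalizer",
    "compute_normalization_factors",
    "apply_normalization",
]

#: intensity columns of the CellMeasurement schema that a factor rescales
VALUE_COLS = ("i_nuclear", "i_cytoplasmic", "i_wholecell")


@dataclass(frozen=True)
class NormalizationFactor:
    image_id: str
    image_mean: float
    global_mean: float

    @property
    def factor(self) -> float:
        return self.global_mean / self.image_mean


def _stacked_values(df: pd.DataFrame, value_cols) -> np.ndarray:
    missing = [c for c in value_cols if c not in df.columns]
    if missing:
        raise InputError(f"measurement table lacks columns {missing}")
    vals = df.loc[:, list(value_cols)].to_numpy(dtype=float).ravel()
    return vals[np.isfinite(vals)]


class IntensityNormalizer(BaseEstimator, TransformerMixin):
    """Fit per-image normalization factors and apply them to a measurement table.

    Parameters
    ----------
    value_cols : tuple of str
        Intensity columns pooled to form the per-image mean; every listed
        column present in the table is rescaled by the same per-image factor
        (one factor per image per channel — nuclear and cytoplasmic means of
        one cell are two observations of the same target channel).
    image_col : str
        Column identifying the source image.
    pool_col : str or None
        Optional column splitting the data into independent normalization
        pools (e.g. condition batches). Default: one pool.
    """

    def __init__(self, value_cols=VALUE_COLS, image_col="image_id", pool_col=None):
        self.value_cols = value_cols
        self.image_col = image_col
        self.pool_col = pool_col

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) == 0:
            raise InputError("cannot fit normalization on an empty table")
        pools = (
            [(None, X)] if self.pool_col is None else list(X.groupby(self.pool_col, sort=True))
        )
        rows = []
        for pool, sub in pools:
            pooled = _stacked_values(sub, self.value_cols)
            if pooled.size == 0:
                raise InputError(f"no finite intensity values in pool {pool!r}")
            global_mean = float(pooled.mean())
            for image_id, img in sub.groupby(self.image_col, sort=True):
                vals = _stacked_values(img, self.value_cols)
                if vals.size == 0 or vals.mean() == 0:
                    raise NormalizationError(
                        f"image {image_id!r} has zero mean intensity; factor undefined"
                    )
                mean = float(vals.mean())
                rows.append(
                    {
                        "pool": pool,
                        "image_id": image_id,
                        "image_mean": mean,
                        "global_mean": global_mean,
                        "factor": global_mean / mean,
                    }
                )
        self.factors_ = pd.DataFrame(rows)
        self.global_mean_ = float(self.factors_["global_mean"].iloc[0])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "factors_"):
            raise InputError("normalizer is not fitted")
        df = X.copy()
        if "normalized" in df.columns and df["normalized"].any():
            raise InputError(
                "table already normalized; re-normalizing is not idempotent and is refused"
            )
        key = self.factors_.set_index(
            "image_id" if self.pool_col is None else ["pool", "image_id"]
        )["factor"]
        if self.pool_col is None:
            idx = df[self.image_col]
        else:
            idx = pd.MultiIndex.from_frame(df[[self.pool_col, self.image_col]])
        factors = key.reindex(idx).to_numpy()
        if np.isnan(factors).any():
            missing = sorted(set(np.asarray(idx)[np.isnan(factors)].tolist()))
            raise InputError(f"no normalization factor for image(s) {missing}")
        for col in self.value_cols:
            if col in df.columns:
                df[col] = df[col].to_numpy(dtype=float) * factors
        df["normalized"] = True
        return df


def compute_normalization_factors(
    measurements: pd.DataFrame,
    value_cols=VALUE_COLS,
    image_col: str = "image_id",
    pool_col: str | None = None,
) -> pd.DataFrame:
    """Per-image factors (``global_mean / image_mean``) as a tidy table."""
    norm = IntensityNormalizer(value_cols=value_cols, image_col=image_col, pool_col=pool_col)
    return norm.fit(measurements).factors_


def apply_normalization(
    measurements: pd.DataFrame,
    factors: pd.DataFrame,
    value_cols=VALUE_COLS,
    image_col: str = "image_id",
) -> pd.DataFrame:
    """Multiply every intensity observation by its image's factor.

    Refuses tables whose ``normalized`` flag is already set.
    """
    norm = IntensityNormalizer(value_cols=value_cols, image_col=image_col)
    norm.factors_ = factors
    norm.global_mean_ = float(factors["global_mean"].iloc[0])
    return norm.transform(measurements)
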