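"""Rank normalisation, the IMD exponential transform, and decile/tercile binning.

These are the shared numerical primitives of the index: every metric,
sub-domain, domain and hazard value is reduced to a normalised mean-rank
R in (0, 1] (1 = most vulnerable / most exposed) before any score or class
is derived from it.  Ties receive their mean rank, so results do not depend
on input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError

__all__ = [
    "RankedSeries",
    "rank_normalise",
    "exponential_transform",
    "decile_rank",
    "tercile_classify",
    "DEFAULT_TRANSFORM_SCALE",
]

#: Scale constant of the exponential transform, as used by the English IMD.
DEFAULT_TRANSFORM_SCALE = 23.0


@dataclass(frozen=True)
class RankedSeries:
    """Normalised ranks of one indicator across areas.

    Attributes
    ----------
    values : pd.Series
        The raw input values (missing entries preserved).
    rank : pd.Series
        Normalised mean-rank R = mean_rank / N over non-missing entries,
        in (0, 1]; NaN where the input is missing.
    tie_sizes : pd.Series
        Number of areas sharing each entry's value (1 where unique).
    direction : int
        +1 if larger raw values rank higher (more vulnerable), -1 if smaller.
    """

    values: pd.Series
    rank: pd.Series
    tie_sizes: pd.Series
    direction: int


def _as_series(values) -> pd.Series:
    if isinstance(values, pd.Series):
        return values.astype(float)
    return pd.Series(np.asarray(values, dtype=float))


def rank_normalise(values, direction: int = 1) -> RankedSeries:
    """Normalised mean-ranks in (0, 1] with 1 = highest under ``direction``.

    Ties get the mean of the ranks they span; missing values are excluded
    from N and propagate as NaN.

    Parameters
    ----------
    values : array-like or pd.Series
        One value per area.
    direction : {+1, -1}
        +1: larger value -> larger rank. -1: order reversed before ranking.
    """
    if direction not in (1, -1):
        raise ParameterError(f"direction must be +1 or -1, got {direction}")
    s = _as_series(values)
    mask = s.notna().to_numpy()
    n = int(mask.sum())
    if n == 0:
        raise ParameterError("rank_normalise requires at least one non-missing value")
    x = s.to_numpy()[mask] * direction
    ranks = rankdata(x, method="average")
    r = np.full(len(s), np.nan)
    r[mask] = ranks / n
    # tie group sizes: count of equal values among non-missing
    ties = np.full(len(s), np.nan)
    _, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    ties[mask] = counts[inv]
    return RankedSeries(
        values=s,
        rank=pd.Series(r, index=s.index),
        tie_sizes=pd.Series(ties, index=s.index),
        direction=direction,
    )


def exponential_transform(rank, scale: float = DEFAULT_TRANSFORM_SCALE):
    """Map normalised ranks R in (0, 1] onto a 0-100 score.

    score = -scale * ln(1 - R * (1 - exp(-100 / scale)))

    Strictly increasing, with score(1) = 100 exactly; small scales spread
    the top (most vulnerable) tail of the ranking across more of the 0-100
    range.  Accepts scalars, arrays or Series; NaN propagates.
    """
    if scale <= 0:
        raise ParameterError(f"scale must be positive, got {scale}")
    r = np.asarray(rank, dtype=float)
    valid = np.isnan(r) | ((r > 0) & (r <= 1))
    if not np.all(valid):
        bad = r[~valid]
        raise ParameterError(f"rank outside (0, 1]: {bad[:5]}")
    score = -scale * np.log(1.0 - r * (1.0 - np.exp(-100.0 / scale)))
    # the closed form gives exactly 100 at R=1; pin the float result to it
    score = np.where(r == 1.0, 100.0, score)
    if isinstance(rank, pd.Series):
        return pd.Series(score, index=rank.index)
    if np.isscalar(rank):
        return float(score)
    return score


def _bin_from_rank(values, k: int) -> pd.Series:
    ranked = rank_normalise(values, direction=1)
    bins = np.ceil(k * ranked.rank.to_numpy())
    out = pd.Series(bins, index=ranked.rank.index)
    return out.astype("Int64") if out.isna().any() else out.astype(int)


def decile_rank(values) -> pd.Series:
    """Decile classes 1..10 from mean-ranks: decile = ceil(10 R); 10 = highest.

    Tied values share a decile; missing values propagate as missing.
    """
    return _bin_from_rank(values, 10)


def tercile_classify(values) -> pd.Series:
    """Tercile classes 1..3 from mean-ranks: tercile = ceil(3 R); 3 = highest."""
    return _bin_from_rank(values, 3)
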