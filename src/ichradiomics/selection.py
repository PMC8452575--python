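"""Iterative correlation-based redundancy filtering of training features.

One pair is removed per iteration: find the pair with the largest absolute
Pearson correlation above the cutoff, drop the member with the larger mean
absolute correlation to all other retained features, recompute, repeat.
This mirrors the find-correlation convention used by common ML toolkits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


def correlation_filter(table: pd.DataFrame, cutoff: float = 0.9) -> list[str]:
    """Return retained feature ids (in original column order).

    Zero-variance columns are dropped up front with a warning (their
    correlation is undefined). Ties: among pairs attaining the maximal |r|,
    the lexicographically first pair by current position; within a pair, equal
    mean absolute correlations remove the later-indexed member.
    """
    if table.shape[1] < 2:
        raise SelectionError("correlation filter needs at least 2 features")
    x = table.to_numpy(dtype=np.float64)
    var = np.nanvar(x, axis=0)
    keep_idx = [i for i in range(x.shape[1]) if var[i] > 1e-12]
    dropped = [c for i, c in enumerate(table.columns) if var[i] <= 1e-12]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s) before filtering",
            stacklevel=2,
        )
    cols = list(table.columns)
    if len(keep_idx) < 2:
        return [cols[i] for i in keep_idx]
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(x[:, keep_idx], rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)

    alive = list(range(len(keep_idx)))
    c = corr.copy()
    while len(alive) > 1:
        sub = c[np.ix_(alive, alive)]
        mx = sub.max()
        if mx <= cutoff:
            break
        # lexicographically first (i, j) attaining the max, i < j in current order
        ii, jj = np.argwhere(sub == mx)[0]
        if ii > jj:
            ii, jj = jj, ii
        mean_i = sub[ii].sum() / (len(alive) - 1)
        mean_j = sub[jj].sum() / (len(alive) - 1)
        drop_pos = ii if mean_i > mean_j else jj
        alive.pop(drop_pos)
    retained = sorted(keep_idx[a] for a in alive)
    return [cols[i] for i in retained]
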