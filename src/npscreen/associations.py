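"""Pairwise Pearson association screen with Bonferroni correction.

Screens clinical features against binarized lesions (and lesions against
lesions) with pairwise-complete Pearson correlations.  Binarized lesions
enter as 0/1 numerics, so a feature-lesion coefficient is the point-
biserial correlation.  Two-sided p-values are compared against a
Bonferroni threshold of 0.05 divided by the number of tested pairs in the
panel (the family is the panel being screened); non-significant entries
are masked.  A hierarchical-clustering column ordering (average linkage on
the correlation distance 1 - r) makes block structure — e.g. an amyloid
block vs a cerebrovascular block of lesions — contiguous in heatmaps.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr

__all__ = ["CorrelationScreen", "correlation_matrix", "order_matrix"]


class CorrelationScreen(NamedTuple):
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample size
    significant: pd.DataFrame
    masked_r: pd.DataFrame  # r where significant, else NaN
    n_tests: int
    alpha: float


def correlation_matrix(
    features: pd.DataFrame,
    lesions: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> CorrelationScreen:
    """Pairwise Pearson r, p and Bonferroni mask for one screen panel.

    With ``lesions`` given the screen is rectangular (feature rows x lesion
    columns); without it, the square symmetric feature-feature screen with
    the family counted over unique off-diagonal pairs.  Zero-variance
    columns yield NaN entries (masked, with a warning).
    """
    rows_df = features.apply(pd.to_numeric, errors="coerce")
    square = lesions is None
    cols_df = rows_df if square else lesions.apply(pd.to_numeric, errors="coerce")
    rnames, cnames = list(rows_df.columns), list(cols_df.columns)
    r = pd.DataFrame(np.nan, index=rnames, columns=cnames)
    p = pd.DataFrame(np.nan, index=rnames, columns=cnames)
    n = pd.DataFrame(0, index=rnames, columns=cnames)
    warned = set()
    for i, a in enumerate(rnames):
        jstart = i if square else 0
        for b in cnames[jstart:]:
            x, yv = rows_df[a], cols_df[b]
            mask = x.notna() & yv.notna()
            m = int(mask.sum())
            n.loc[a, b] = m
            if square:
                n.loc[b, a] = m
            if m < 3:
                continue
            xs, ys = x[mask].to_numpy(float), yv[mask].to_numpy(float)
            if xs.std() == 0.0 or ys.std() == 0.0:
                key = a if xs.std() == 0.0 else b
                if key not in warned:
                    warnings.warn(f"zero-variance column {key!r}: correlation undefined")
                    warned.add(key)
                continue
            rv, pv = pearsonr(xs, ys)
            r.loc[a, b], p.loc[a, b] = rv, pv
            if square:
                r.loc[b, a], p.loc[b, a] = rv, pv
    if square:
        n_tests = len(rnames) * (len(rnames) - 1) // 2
    else:
        n_tests = len(rnames) * len(cnames)
    threshold = alpha / max(n_tests, 1)
    sig = p < threshold
    if square:
        np.fill_diagonal(sig.values, False)  # self-correlations are not tests
    masked = r.where(sig)
    return CorrelationScreen(r, p, n, sig, masked, n_tests, threshold)


def order_matrix(r: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Hierarchical-clustering leaf order for rows and columns of an r-matrix.

    Square symmetric matrices are ordered once on the correlation distance
    ``1 - r``; rectangular matrices order rows and columns separately on
    the euclidean distance between their correlation profiles.  NaNs are
    treated as zero correlation for ordering purposes; an all-NaN matrix is
    an error.
    """
    vals = r.to_numpy(dtype=float)
    if np.isnan(vals).all():
        raise ValueError("correlation matrix is all-NaN; nothing to order")
    filled = np.nan_to_num(vals, nan=0.0)
    is_square = r.shape[0] == r.shape[1] and list(r.index) == list(r.columns)
    if is_square and np.allclose(filled, filled.T, atol=1e-12):
        d = 1.0 - filled
        np.fill_diagonal(d, 0.0)
        # condensed distance vector for linkage
        iu = np.triu_indices_from(d, k=1)
        order = leaves_list(linkage(d[iu], method="average"))
        labels = [r.index[i] for i in order]
        return labels, labels
    row_order = leaves_list(linkage(filled, method="average")) if r.shape[0] > 1 else [0]
    col_order = leaves_list(linkage(filled.T, method="average")) if r.shape[1] > 1 else [0]
    return [r.index[i] for i in row_order], [r.columns[i] for i in col_order]
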