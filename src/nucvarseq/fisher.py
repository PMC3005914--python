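"""Fisher-criterion (F-score) ranking of k-mer features.

For feature j with class means m1, m2, overall mean m and unbiased
within-class scatters s1, s2 (s_k = 1/(n_k-1) * sum (x - m_k)^2), the
F-score is

    F(j) = ((m1 - m)^2 + (m2 - m)^2) / (s1 + s2).

Larger F means stronger between-class separation relative to within-class
scatter. Each motif is annotated with the class direction its mean is
higher in: "+" for the +1 class, "-" for the -1 class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kmers import KmerIndex, LabeledDataset


def fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized F-score of every column of X under ±1 labels ``y``.

    Features with zero pooled scatter get F = 0 when the class means agree
    and F = +inf when they differ (maximal separation).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    m1_mask, m2_mask = y > 0, y <= 0
    n1, n2 = int(m1_mask.sum()), int(m2_mask.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 members")
    m = X.mean(axis=0)
    m1 = X[m1_mask].mean(axis=0)
    m2 = X[m2_mask].mean(axis=0)
    s1 = ((X[m1_mask] - m1) ** 2).sum(axis=0) / (n1 - 1)
    s2 = ((X[m2_mask] - m2) ** 2).sum(axis=0) / (n2 - 1)
    num = (m1 - m) ** 2 + (m2 - m) ** 2
    denom = s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / denom
    f[(denom == 0) & (num == 0)] = 0.0
    f[(denom == 0) & (num > 0)] = np.inf
    return f


def fisher_score(column, labels) -> float:
    """F-score of a single feature column."""
    return float(fisher_scores(np.asarray(column, dtype=np.float64)[:, None], labels)[0])


def rank_features(
    data: LabeledDataset, index: KmerIndex, top: int = 20
) -> pd.DataFrame:
    """Score and rank every canonical k-mer feature.

    Returns a DataFrame sorted by descending F-score (ties broken by feature
    index order) with columns motif, k, fscore, direction, mean_class1,
    mean_class2 and rank; ``df.attrs["top"]`` holds the top-n view.
    """
    f = fisher_scores(data.X, data.y)
    m1 = data.X[data.y > 0].mean(axis=0)
    m2 = data.X[data.y <= 0].mean(axis=0)
    df = pd.DataFrame(
        {
            "motif": index.kmers,
            "k": [len(m) for m in index.kmers],
            "fscore": f,
            "direction": np.where(m1 >= m2, "+", "-"),
            "mean_class1": m1,
            "mean_class2": m2,
        }
    )
    order = np.lexsort((np.arange(len(f)), -f))  # stable: ties keep index order
    df = df.iloc[order].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["top"] = df.head(top).copy()
    return df


def format_top_table(df: pd.DataFrame, top: int = 20) -> pd.DataFrame:
    """Top-n view with the conventional columns Order/Motif/F-score/Direction."""
    head = df.head(top)
    return pd.DataFrame(
        {
            "Order": head["rank"].values,
            "Motif": head["motif"].values,
            "F-score": head["fscore"].values,
            "Direction": head["direction"].values,
        }
    )
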