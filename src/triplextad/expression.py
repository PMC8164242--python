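"""Expressed-lncRNA selection, expression clustering, and cluster ANOVA.

"Expressed" means TPM strictly greater than the threshold (default 5).
Clustering standardises each lncRNA's TPM profile to z-scores across cell
lines and applies agglomerative clustering with correlation distance and
average linkage; the number of clusters can be fixed or chosen by maximising
the silhouette over a range.  A one-way ANOVA then asks whether a per-lncRNA
triplex statistic (TFS count, TFD count, TFD length) depends on cluster
membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score


def filter_expressed(tpm: pd.DataFrame, threshold: float = 5.0
                     ) -> tuple[dict[str, set[str]], set[str]]:
    """Per-cell-line sets of expressed lncRNA ids (TPM > threshold) and their union."""
    if threshold < 0:
        raise ValueError("threshold must be ≥ 0")
    per_line = {col: set(tpm.index[tpm[col] > threshold]) for col in tpm.columns}
    union = set().union(*per_line.values()) if per_line else set()
    return per_line, union


def zscore_rows(tpm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores; constant rows map to all-zeros (rows are kept aligned)."""
    x = tpm.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(x - mean, sd, out=np.zeros_like(x), where=sd > 0)
    return pd.DataFrame(z, index=tpm.index, columns=tpm.columns)


def _correlation_distance(z: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between rows; all-zero rows get distance 1 to
    everything except other all-zero rows (distance 0)."""
    norms = np.linalg.norm(z, axis=1)
    zero = norms == 0
    zn = np.divide(z, norms[:, None], out=np.zeros_like(z), where=norms[:, None] > 0)
    corr = zn @ zn.T
    d = 1.0 - corr
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    d[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    labels: pd.Series
    k: int
    silhouette: float | None


def zscore_and_cluster(tpm: pd.DataFrame, k: int | None = None,
                       k_range: range = range(2, 13)) -> ClusterResult:
    """Standardise rows and cluster the z-score profiles.

    With ``k=None`` the cluster count maximising the silhouette (on the
    correlation-distance matrix) over ``k_range`` is used.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need ≥ 2 cell lines to cluster")
    z = zscore_rows(tpm)
    n = len(z)
    if n == 1:
        return ClusterResult(z, pd.Series([0], index=tpm.index, name="cluster"), 1, None)
    d = _correlation_distance(z.to_numpy())

    def fit(kk: int) -> np.ndarray:
        model = AgglomerativeClustering(n_clusters=kk, metric="precomputed", linkage="average")
        return model.fit_predict(d)

    if k is not None:
        labels = fit(k)
        sil = silhouette_score(d, labels, metric="precomputed") if 1 < k < n else None
    else:
        best = None
        for kk in k_range:
            if not (1 < kk < n):
                continue
            lab = fit(kk)
            if len(set(lab)) < 2:
                continue
            s = silhouette_score(d, lab, metric="precomputed")
            if best is None or s > best[0]:
                best = (s, kk, lab)
        if best is None:
            raise ValueError("no valid k in k_range")
        sil, k, labels = best[0], best[1], best[2]
    return ClusterResult(z, pd.Series(labels, index=tpm.index, name="cluster"), int(k),
                         None if sil is None else float(sil))


def anova_by_cluster(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """One-way ANOVA of a per-lncRNA statistic across expression clusters."""
    aligned = pd.DataFrame({"v": values, "g": labels}).dropna()
    groups = [sub["v"].to_numpy(float) for _, sub in aligned.groupby("g")]
    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups for ANOVA")
    for gname, sub in aligned.groupby("g"):
        if len(sub) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 members")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):      # all groups identical and zero within-variance
        return 0.0, 1.0
    return float(f), float(p)
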