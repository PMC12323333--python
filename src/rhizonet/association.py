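"""Taxa-group <-> trait association: Mantel tests and correlation heatmaps.

The Mantel test correlates the upper triangles of two sample distance
matrices and assesses significance by permuting sample labels of one
matrix (seeded, two-sided by default, exhaustive enumeration available for
tiny matrices).  Heatmaps are cellwise Spearman correlations between
feature columns (taxa or taxa-group abundances) and trait columns, with
raw-p significance stars (* p<0.05, ** p<0.01, *** p<0.001) and
Benjamini-Hochberg q-values over the whole matrix reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import ValidationError


@dataclass
class MantelResult:
    label_a: str
    label_b: str
    method: str
    r: float
    p: float
    n_permutations: int
    seed: int | None


def _check_distance(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"{name} is not square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError(f"{name} is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError(f"{name} has a non-zero diagonal")


def mantel(dist_a, dist_b, method: str = "spearman", n_perm: int = 999,
           seed: int | None = None, alternative: str = "two-sided",
           permutations: str = "random",
           labels: tuple[str, str] = ("A", "B")) -> MantelResult:
    """Mantel test between two sample distance matrices.

    r is the Spearman (default) or Pearson correlation of the upper
    triangles.  p = (1 + #{permuted statistic >= observed}) / (1 + n_perm),
    where the statistic is |r| for the two-sided test and r for
    ``alternative='greater'``.  ``permutations='exhaustive'`` enumerates
    all n! relabelings (feasible only for tiny n) and then p is the exact
    fraction over all relabelings.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    _check_distance(a, "dist_a")
    _check_distance(b, "dist_b")
    if a.shape != b.shape:
        raise ValidationError("distance matrices have mismatched sample sets")
    n = a.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples")
    iu = np.triu_indices(n, k=1)

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        if method == "pearson":
            return stats.pearsonr(x, y).statistic
        raise ValidationError(f"unknown method {method!r}")

    va, vb = a[iu], b[iu]
    r_obs = float(corr(va, vb))
    stat = abs(r_obs) if alternative == "two-sided" else r_obs

    # relabeling only permutes which condensed entries pair up, so the
    # permuted statistic is a gather of precomputed (rank-)values followed
    # by one dot product: x-multiset moments are permutation-invariant
    if method == "spearman":
        xv = stats.rankdata(va)
        yv = stats.rankdata(vb)
    else:
        xv, yv = va.astype(float), vb.astype(float)
    yc = yv - yv.mean()
    norm_y = math.sqrt((yc ** 2).sum())
    xc_norm = math.sqrt(((xv - xv.mean()) ** 2).sum())
    pair_index = np.zeros((n, n), dtype=np.intp)
    pair_index[iu] = np.arange(len(va))
    pair_index = pair_index + pair_index.T

    def perm_stat(perm) -> float:
        gathered = xv[pair_index[np.ix_(perm, perm)][iu]]
        r = float(gathered @ yc) / (xc_norm * norm_y)
        return abs(r) if alternative == "two-sided" else r

    if permutations == "exhaustive":
        if n > 8:
            raise ValidationError("exhaustive enumeration limited to n <= 8")
        vals = np.array([perm_stat(np.array(pm))
                         for pm in iter_permutations(range(n))])
        p = float((vals >= stat - 1e-12).mean())
        n_used = len(vals)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if perm_stat(rng.permutation(n)) >= stat - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(labels[0], labels[1], method, r_obs, p, n_used, seed)


def distance_matrix(features: pd.DataFrame, metric: str = "euclidean"
                    ) -> pd.DataFrame:
    """Samples x samples distance matrix from a samples x features table.

    ``metric`` is any scipy pdist metric; "braycurtis" is the usual
    full-community choice, "euclidean" the default for low-dimensional
    group-abundance vectors.
    """
    d = squareform(pdist(features.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(d, index=features.index, columns=features.index)


def group_abundance(proportions: pd.DataFrame, genera) -> pd.Series:
    """Per-sample summed relative abundance of a genus set."""
    genera = list(genera)
    if not genera:
        raise ValidationError("genus set is empty")
    missing = [g for g in genera if g not in proportions.index]
    if missing:
        raise ValidationError(f"unknown genera: {missing}")
    return proportions.loc[genera].sum(axis=0)


STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_from_p(p: float) -> str:
    if np.isnan(p):
        return ""
    for cutoff, mark in STAR_LEVELS:
        if p < cutoff:
            return mark
    return ""


@dataclass
class AssociationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    stars: pd.DataFrame


def group_trait_heatmap(features: pd.DataFrame, traits: pd.DataFrame,
                        method: str = "spearman") -> AssociationMatrix:
    """Cellwise correlation between features and traits (rows = samples).

    Constant features or traits give NaN cells (flagged missing, never 0).
    Stars follow raw p (matching common figure legends); BH q over all
    defined cells is reported alongside.
    """
    shared = features.index.intersection(traits.index)
    if len(shared) < 4:
        raise ValidationError("need at least 4 shared samples")
    f = features.loc[shared]
    t = traits.loc[shared]
    rho = pd.DataFrame(index=f.columns, columns=t.columns, dtype=float)
    pmat = pd.DataFrame(index=f.columns, columns=t.columns, dtype=float)
    for fc in f.columns:
        x = f[fc].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        for tc in t.columns:
            y = t[tc].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            if method == "spearman":
                res = stats.spearmanr(x, y)
            elif method == "pearson":
                res = stats.pearsonr(x, y)
            else:
                raise ValidationError(f"unknown method {method!r}")
            rho.loc[fc, tc] = float(res.statistic)
            pmat.loc[fc, tc] = float(res.pvalue)
    flat = pmat.to_numpy().ravel()
    ok = ~np.isnan(flat)
    qflat = np.full_like(flat, np.nan)
    if ok.any():
        qflat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    q = pd.DataFrame(qflat.reshape(pmat.shape), index=pmat.index,
                     columns=pmat.columns)
    stars = pmat.map(stars_from_p)
    return AssociationMatrix(rho, pmat, q, stars)
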