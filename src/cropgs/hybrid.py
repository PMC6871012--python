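"""Hybrid-performance prediction with additive + dominance RR-BLUP.

For a hybrid of two inbred parents with dosages d1, d2 in {0, 2} per
marker, the additive design entry is Z_A = (d1 + d2)/2 - 1 in {-1, 0, 1}
and the dominance entry Z_D = 1 iff the parents carry different homozygous
genotypes. The model

    y = 1*mu + Z_A a + Z_D d + e,   a_i ~ N(0, s2_a), d_i ~ N(0, s2_d)

is solved in its kernel (dual) form with V = s2_a Z_A Z_A' +
s2_d Z_D Z_D' + s2_e I; variance components default to two-kernel EM-REML.
Fitted marker effects rank all candidate single crosses; the top fraction
is selected and a hierarchical clustering of the predicted parent x parent
performance matrix proposes heterotic groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, RegressorMixin

from .quantgen import em_reml_kernels
from .variants import VariantMatrix


def enumerate_crosses(parent_ids, restrict_between_groups: bool = False,
                      groups=None):
    """All unordered parent pairs (i < j); optionally only between-group
    (B x R) pairs. Duplicate ids raise."""
    ids = list(parent_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate parent ids")
    if len(ids) < 2:
        raise ValueError("need >= 2 parents")
    if restrict_between_groups:
        if groups is None:
            raise ValueError("groups required when restricting")
        g = dict(zip(ids, groups))
        return [(a, b) for k, a in enumerate(ids) for b in ids[k + 1:]
                if g[a] != g[b]]
    return [(a, b) for k, a in enumerate(ids) for b in ids[k + 1:]]


def hybrid_design(parents: VariantMatrix, pairs):
    """Additive/dominance design rows for a list of parent pairs.

    Returns ``(Z_A, Z_D)`` with one row per pair: Z_A in {-1, 0, 1},
    Z_D in {0, 1}. Parents must be fully inbred (dosage 0/2).
    """
    d = parents.dosage
    if not np.isin(d, (0.0, 2.0)).all():
        raise ValueError("parents must be inbred (dosage 0/2, no missing); "
                         "heterozygous parents give ambiguous gametes")
    index = {s: i for i, s in enumerate(parents.sample_ids)}
    za = np.empty((len(pairs), parents.n_variants))
    zd = np.empty_like(za)
    for r, (p1, p2) in enumerate(pairs):
        d1, d2 = d[index[p1]], d[index[p2]]
        za[r] = (d1 + d2) / 2.0 - 1.0
        zd[r] = (d1 != d2).astype(float)
    return za, zd


class AdditiveDominanceBLUP(BaseEstimator, RegressorMixin):
    """Additive + dominance RR-BLUP as a scikit-learn regressor.

    ``fit(X, y)`` takes the hybrid dosage matrix X (values 0/1/2 from
    crossing inbreds), from which Z_A = X - 1 and Z_D = 1{X == 1}.

    Parameters
    ----------
    var_components : tuple (s2_a, s2_d, s2_e), optional
        Fixed variance components; two-kernel EM-REML when None.

    Attributes (after fit)
    ----------------------
    mu_ : fitted mean
    a_, d_ : per-marker additive and dominance effects
    sigma2_a_, sigma2_d_, sigma2_e_ : variance components
    """

    def __init__(self, var_components=None):
        self.var_components = var_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 hybrids")
        za = X - 1.0
        zd = (X == 1.0).astype(float)
        ka = za @ za.T
        kd = zd @ zd.T
        if self.var_components is None:
            # per-marker scaling: u = Z a with q = n_markers levels each
            comps = em_reml_kernels(
                y, kernels=[ka, kd], q_levels=[X.shape[1], X.shape[1]])
            s2a, s2d, s2e = comps
        else:
            s2a, s2d, s2e = self.var_components
        if s2a == 0 and s2d == 0:
            raise ValueError("no genetic model: sigma2_a = sigma2_d = 0")
        n = len(y)
        V = s2a * ka + s2d * kd + max(s2e, 1e-10) * np.eye(n)
        ones = np.ones(n)
        sol = np.linalg.solve(V, np.column_stack([ones, y]))
        mu = float(ones @ sol[:, 1] / (ones @ sol[:, 0]))
        alpha = sol[:, 1] - sol[:, 0] * mu
        self.mu_ = mu
        self.a_ = s2a * (za.T @ alpha)
        self.d_ = s2d * (zd.T @ alpha)
        self.sigma2_a_, self.sigma2_d_, self.sigma2_e_ = \
            float(s2a), float(s2d), float(s2e)
        self.n_markers_ = X.shape[1]
        return self

    def predict(self, X=None, Z_A=None, Z_D=None):
        """Predict from hybrid dosages X, or directly from design rows."""
        if X is not None:
            X = np.asarray(X, dtype=float)
            Z_A, Z_D = X - 1.0, (X == 1.0).astype(float)
        if Z_A.shape[1] != self.n_markers_:
            raise ValueError("marker count mismatch with fitted model")
        return self.mu_ + Z_A @ self.a_ + Z_D @ self.d_


def fit_ad_rrblup(y, Z_A, Z_D, varcomp=None) -> AdditiveDominanceBLUP:
    """Functional fit from explicit design matrices (rows per hybrid)."""
    Z_A = np.asarray(Z_A, dtype=float)
    Z_D = np.asarray(Z_D, dtype=float)
    X = np.where(Z_D == 1.0, 1.0, Z_A + 1.0)  # back to hybrid dosage
    return AdditiveDominanceBLUP(var_components=varcomp).fit(X, y)


def predict_hybrids(model: AdditiveDominanceBLUP, parents: VariantMatrix,
                    pairs, batch: int = 20_000) -> pd.DataFrame:
    """Predicted genotypic value for each candidate cross, ranked descending.

    Returns a DataFrame (parent1, parent2, predicted, rank); ties keep the
    enumeration (pair-id) order, so ranking is deterministic.
    """
    preds = np.empty(len(pairs))
    for lo in range(0, len(pairs), batch):
        za, zd = hybrid_design(parents, pairs[lo:lo + batch])
        preds[lo:lo + batch] = model.predict(Z_A=za, Z_D=zd)
    df = pd.DataFrame(pairs, columns=["parent1", "parent2"])
    df["predicted"] = preds
    order = np.lexsort((np.arange(len(df)), -df["predicted"].to_numpy()))
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return df.sort_values("rank").reset_index(drop=True)


def select_top(pred: pd.DataFrame, fraction: float = 0.001,
               tested_list=None) -> pd.DataFrame:
    """Flag the top ``ceil(fraction * N)`` crosses by predicted value
    (ties at the cutoff value all included) and mark previously tested
    parent pairs."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    df = pred.copy()
    k = int(np.ceil(fraction * len(df)))
    cutoff = df["predicted"].nlargest(k).iloc[-1]
    df["selected"] = df["predicted"] >= cutoff
    tested = {frozenset(p) for p in (tested_list or [])}
    df["previously_tested"] = [
        frozenset((a, b)) in tested
        for a, b in zip(df["parent1"], df["parent2"])
    ]
    return df


def cross_validate_hybrids(X, y, train_size: int = 48, runs: int = 500,
                           h2: float = 1.0, seed: int = 0,
                           var_components=None):
    """Repeated random-split cross-validation of the A+D model.

    Per run, ``train_size`` hybrids train the model and the rest are
    predicted; accuracy is the Pearson correlation between predicted and
    observed values in the test set, standardised by sqrt(h2). Returns a
    dict with per-run accuracies and summary statistics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not (2 <= train_size <= n - 2):
        raise ValueError("train_size must leave >= 2 test hybrids")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    if var_components is None:
        base = AdditiveDominanceBLUP().fit(X, y)
        var_components = (base.sigma2_a_, base.sigma2_d_, base.sigma2_e_)
    rng = np.random.default_rng(seed)
    rs = np.empty(runs)
    for run in range(runs):
        perm = rng.permutation(n)
        tr, te = perm[:train_size], perm[train_size:]
        model = AdditiveDominanceBLUP(var_components=var_components) \
            .fit(X[tr], y[tr])
        rs[run] = np.corrcoef(model.predict(X[te]), y[te])[0, 1]
    return {
        "r_per_run": rs,
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)) if runs > 1 else 0.0,
        "mean_standardized": float(rs.mean() / np.sqrt(h2)),
        "h2": h2, "runs": runs, "train_size": train_size,
        "test_size": n - train_size, "seed": seed,
    }


def heterotic_groups(pred: pd.DataFrame, parent_ids, k_groups: int = 2,
                     linkage: str = "average"):
    """Heterotic-group discovery from the predicted-performance matrix.

    Builds the symmetric parents x parents matrix of predicted cross
    values (selfs excluded; missing pairs imputed with row means),
    hierarchically clusters its rows (Euclidean, configurable linkage)
    and cuts at ``k_groups``. The inter-group gain is

        100 * (mean predicted value of inter-group crosses /
               mean over all crosses - 1).

    Returns ``(assignment, gain_percent)`` with ``assignment`` a Series
    mapping parent id -> group label (1..k).
    """
    ids = list(parent_ids)
    if k_groups > len(ids):
        raise ValueError("more groups than parents")
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    M = np.full((n, n), np.nan)
    for a, b, v in zip(pred["parent1"], pred["parent2"], pred["predicted"]):
        if a in pos and b in pos and a != b:
            M[pos[a], pos[b]] = M[pos[b], pos[a]] = v
    row_means = np.nanmean(M, axis=1)
    missing = np.isnan(M)
    M[missing] = ((row_means[:, None] + row_means[None, :]) / 2.0)[missing]
    np.fill_diagonal(M, row_means)

    Z = scipy_linkage(M, method=linkage, metric="euclidean")
    labels = fcluster(Z, t=k_groups, criterion="maxclust")
    assignment = pd.Series(labels, index=ids, name="group")

    iu = np.triu_indices(n, k=1)
    inter = labels[iu[0]] != labels[iu[1]]
    all_mean = M[iu].mean()
    gain = 100.0 * (M[iu][inter].mean() / all_mean - 1.0) if inter.any() \
        else 0.0
    if np.allclose(M[iu], M[iu][0]):
        gain = 0.0
    return assignment, float(gain)
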