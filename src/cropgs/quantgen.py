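"""Linear mixed models for trial data, heritability, and single-marker GWAS.

Variance components of models with independent random factors are
estimated by EM-REML (non-negative by construction, matching the closed
ANOVA forms on balanced designs); genotype BLUEs come from GLS at the
converged components. Heritability/repeatability ratios follow the
standard line-mean forms:

    h2 (line mean)  = s2_G / (s2_G + s2_GY/y + s2_GS/s + s2_GYS/(ys)
                              + s2_e/(y*s*r))
    H2 (broad)      = s2_G / (s2_G + s2_GE/l + s2_e/(l*r))
    w2 (repeatab.)  = s2_G / (s2_G + s2_e/N_R)

GWAS is the fixed-effects AOV route: per SNP a linear model with a block
(maturity-group) effect plus the additive dosage, F-tested with 1 df,
Benjamini-Hochberg corrected (q <= 0.001) with an additional hard p <
1e-10 flag, and a QQ/genomic-inflation calibration check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .variants import VariantMatrix


# -- EM-REML core ------------------------------------------------------------

def em_reml_kernels(y, kernels, q_levels, X=None, start=None,
                    tol: float = 1e-9, max_iter: int = 100):
    """EM-REML for y = X b + sum_k u_k + e with Cov(u_k) = s2_k K_k.

    ``q_levels[k]`` is the effective number of levels behind kernel k
    (len(u_k) when K_k = Z_k Z_k'). Returns the list of variance
    components [s2_1, ..., s2_K, s2_e]. Estimates are non-negative by
    construction; convergence is on the maximum component change relative
    to the total variance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    kernels = [np.asarray(K, dtype=float) for K in kernels]
    vy = np.var(y, ddof=1) if n > 1 else 1.0
    theta = list(start) if start is not None else \
        [vy / (len(kernels) + 1)] * (len(kernels) + 1)
    eye = np.eye(n)
    all_k = kernels + [eye]
    all_q = list(q_levels) + [n]
    decaying = [0] * len(all_k)
    prev = [None] * len(all_k)
    for _ in range(max_iter):
        V = sum(t * K for t, K in zip(theta, all_k))
        Vi = np.linalg.inv(V + 1e-12 * eye)
        XtVi = X.T @ Vi
        P = Vi - XtVi.T @ np.linalg.solve(XtVi @ X, XtVi)
        alpha = P @ y
        new = []
        for t, K, q in zip(theta, all_k, all_q):
            Ka = K @ alpha
            val = (t ** 2 * (alpha @ Ka) + t * q - t ** 2 * np.sum(P * K)) / q
            new.append(max(val, 0.0))
        total = sum(new) + 1e-12
        # snap components decaying toward the zero boundary to exactly zero
        # (zero is absorbing under the EM update, so this is a boundary fit);
        # EM approaches the boundary geometrically, so a component that has
        # shrunk monotonically for many iterations and is negligible is dead
        for i, (v, t) in enumerate(zip(new, theta)):
            decaying[i] = decaying[i] + 1 if v < t else 0
            snap = v < 1e-8 * total
            if not snap and decaying[i] >= 10 and v < 1e-3 * total \
                    and prev[i] is not None:
                # geometric decay: Aitken-extrapolate the limit; a limit at
                # or below zero means the component is heading to the
                # boundary, which is absorbing under the EM update
                d1, d0 = t - v, prev[i] - t
                if 0 < d1 < d0:
                    rate = d1 / d0
                    limit = v - d1 * rate / (1 - rate)
                    snap = limit < 1e-6 * total
            if snap:
                new[i] = 0.0
            prev[i] = t
        delta = max(abs(a - b) for a, b in zip(new, theta)) / total
        theta = new
        if delta < tol:
            break
    else:
        # EM converges only geometrically near flat optima: polish the
        # still-positive components by quasi-Newton on the restricted
        # likelihood (log-parametrised, so non-negativity is preserved);
        # components EM sent to the zero boundary stay there
        theta = _polish_reml(y, all_k, X, theta)
    return theta


def _neg_rll_and_grad(log_t, y, kernels, X, active):
    t = np.exp(log_t)
    n = len(y)
    V = sum(tt * kernels[i] for tt, i in zip(t, active))
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    W = np.linalg.solve(XtVi @ X, XtVi)
    P = Vi - XtVi.T @ W
    alpha = P @ y
    sign, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtVi @ X)
    nll = 0.5 * (logdet_v + logdet_x + y @ alpha)
    grad = np.array([
        0.5 * (np.sum(P * kernels[i]) - alpha @ kernels[i] @ alpha) * tt
        for tt, i in zip(t, active)])
    return nll, grad


def _polish_reml(y, kernels, X, theta):
    from scipy.optimize import minimize

    active = [i for i, t in enumerate(theta) if t > 0]
    if not active:
        return theta
    x0 = np.log([theta[i] for i in active])
    res = minimize(_neg_rll_and_grad, x0, args=(y, kernels, X, active),
                   jac=True, method="L-BFGS-B",
                   bounds=[(-30.0, 30.0)] * len(active))
    out = list(theta)
    for i, v in zip(active, np.exp(res.x)):
        out[i] = float(v) if v > 1e-12 else 0.0
    return out


def _one_hot(values):
    codes, levels = pd.factorize(values, sort=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, list(levels)


def _term_labels(records, term):
    cols = term.split(":")
    lab = records[cols[0]].astype(str)
    for c in cols[1:]:
        lab = lab + "|" + records[c].astype(str)
    return lab


@dataclass
class LmmResult:
    varcomp: dict                       # term -> variance (incl. "residual")
    blues: pd.Series | None             # genotype BLUEs when genotype fixed
    beta: np.ndarray = field(repr=False, default=None)
    fixed_names: list = field(default_factory=list)
    n_iter_info: str = ""


def fit_lmm(records: pd.DataFrame, response: str = "value",
            fixed=("genotype",), random=("replication", "block"),
            covariates=(), tol: float = 1e-9,
            max_iter: int = 100) -> LmmResult:
    """Mixed model on tidy trial records.

    ``fixed`` and ``random`` name factor columns (interactions as
    "a:b"); ``covariates`` are numeric fixed regressors. Variance
    components of the random terms (plus the residual) are EM-REML
    estimates; if "genotype" is a fixed term its GLS coefficients are the
    genotype BLUEs (cell-mean parametrisation, other fixed factors
    baseline-coded).
    """
    y = records[response].to_numpy(dtype=float)
    n = len(y)
    blocks, names = [], []
    genotype_levels = None
    for k, term in enumerate(fixed):
        Z, levels = _one_hot(_term_labels(records, term))
        if k == 0:
            blocks.append(Z)            # cell means for the first term
            names += [f"{term}[{l}]" for l in levels]
            if term == "genotype":
                genotype_levels = levels
        else:
            blocks.append(Z[:, 1:])     # drop first level
            names += [f"{term}[{l}]" for l in levels[1:]]
    for cov in covariates:
        blocks.append(records[cov].to_numpy(dtype=float)[:, None])
        names.append(cov)
    if not blocks:
        blocks = [np.ones((n, 1))]
        names = ["intercept"]
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first term whose addition fails to raise the rank
        acc, r_prev = None, 0
        for j, term in enumerate(fixed):
            Zt, lv = _one_hot(_term_labels(records, term))
            Zt = Zt if j == 0 else Zt[:, 1:]
            acc = Zt if acc is None else np.hstack([acc, Zt])
            r = np.linalg.matrix_rank(acc)
            if r < r_prev + Zt.shape[1]:
                raise ValueError(f"fixed term '{term}' is not estimable "
                                 "(confounded with earlier terms)")
            r_prev = r
        raise ValueError("fixed design is rank deficient")

    kernels, q_levels, terms = [], [], []
    for term in random:
        Z, levels = _one_hot(_term_labels(records, term))
        if len(levels) < 2:
            raise ValueError(f"random term '{term}' has < 2 levels")
        kernels.append(Z @ Z.T)
        q_levels.append(len(levels))
        terms.append(term)

    if kernels:
        theta = em_reml_kernels(y, kernels, q_levels, X=X,
                                tol=tol, max_iter=max_iter)
    else:
        # OLS residual variance
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        theta = [float(resid @ resid) / max(n - X.shape[1], 1)]
    varcomp = dict(zip(terms, theta[:-1]))
    varcomp["residual"] = theta[-1]

    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V = V + t * K
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
    blues = None
    if genotype_levels is not None:
        blues = pd.Series(beta[:len(genotype_levels)], index=genotype_levels,
                          name="BLUE")
    return LmmResult(varcomp=varcomp, blues=blues, beta=beta,
                     fixed_names=names)


# -- heritability ratios -----------------------------------------------------

def heritability_line_mean(sigma2_g, sigma2_gy, sigma2_gs, sigma2_gys,
                           sigma2_e, n_years, n_stresses, n_reps) -> float:
    """Line-mean heritability for a genotype x year x stress trial."""
    comps = (sigma2_g, sigma2_gy, sigma2_gs, sigma2_gys, sigma2_e)
    if any(c < 0 for c in comps):
        raise ValueError("variance components must be >= 0")
    denom = (sigma2_g + sigma2_gy / n_years + sigma2_gs / n_stresses
             + sigma2_gys / (n_years * n_stresses)
             + sigma2_e / (n_years * n_stresses * n_reps))
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def heritability_broad(sigma2_g, sigma2_ge, sigma2_e, n_envs,
                       n_reps) -> float:
    """Broad-sense heritability across environments:
    H2 = s2_G / (s2_G + s2_GE/l + s2_e/(l*r))."""
    if min(sigma2_g, sigma2_ge, sigma2_e) < 0:
        raise ValueError("variance components must be >= 0")
    denom = sigma2_g + sigma2_ge / n_envs + sigma2_e / (n_envs * n_reps)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def repeatability(sigma2_g, sigma2_e, n_reps) -> float:
    """Within-environment repeatability w2 = s2_G / (s2_G + s2_e/N_R)."""
    if n_reps < 1:
        raise ValueError("N_R must be >= 1")
    denom = sigma2_g + sigma2_e / n_reps
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def filter_environments(env_components: pd.DataFrame,
                        threshold: float = 0.5) -> list:
    """Keep environments whose repeatability reaches the threshold.

    ``env_components`` needs columns environment, sigma2_g, sigma2_e,
    n_reps. Returns the kept environment names.
    """
    kept = []
    for _, row in env_components.iterrows():
        w2 = repeatability(row["sigma2_g"], row["sigma2_e"], row["n_reps"])
        if w2 >= threshold:
            kept.append(row["environment"])
    return kept


# -- balanced-design ANOVA closed forms --------------------------------------

def anova_one_way(records: pd.DataFrame, group: str = "genotype",
                  response: str = "value"):
    """Method-of-moments components for a balanced one-way random design:
    s2_e = MSE, s2_g = (MSG - MSE)/r."""
    g = records.groupby(group)[response]
    counts = g.count()
    if counts.nunique() != 1:
        raise ValueError("design is not balanced")
    r = int(counts.iloc[0])
    means = g.mean()
    grand = records[response].mean()
    msg = r * ((means - grand) ** 2).sum() / (len(means) - 1)
    mse = ((records[response] - records[group].map(means)) ** 2).sum() / \
        (len(records) - len(means))
    return max((msg - mse) / r, 0.0), float(mse)


def anova_line_mean_h2(records: pd.DataFrame, response: str = "value"):
    """ANOVA line-mean heritability for a balanced genotype x year x
    stress x replication trial: h2 = (MS_G - MS_GY - MS_GS + MS_GYS)/MS_G.

    Follows from the balanced expected mean squares, since
    MS_G/(r*y*s) estimates the full line-mean denominator.
    """
    df = records
    g_means = df.groupby("genotype")[response].mean()
    y_means = df.groupby("year")[response].mean()
    s_means = df.groupby("stress")[response].mean()
    gy = df.groupby(["genotype", "year"])[response].mean()
    gs = df.groupby(["genotype", "stress"])[response].mean()
    ys = df.groupby(["year", "stress"])[response].mean()
    gys = df.groupby(["genotype", "year", "stress"])[response].mean()
    grand = df[response].mean()
    ng, ny, ns = len(g_means), len(y_means), len(s_means)
    r = len(df) / (ng * ny * ns)

    gy_dev = gy - g_means.reindex(gy.index.get_level_values(0)).to_numpy() \
        - y_means.reindex(gy.index.get_level_values(1)).to_numpy() + grand
    gs_dev = gs - g_means.reindex(gs.index.get_level_values(0)).to_numpy() \
        - s_means.reindex(gs.index.get_level_values(1)).to_numpy() + grand
    gys_dev = (gys
               - gy.reindex(gys.index.droplevel("stress")).to_numpy()
               - gs.reindex(gys.index.droplevel("year")).to_numpy()
               - ys.reindex(gys.index.droplevel("genotype")).to_numpy()
               + g_means.reindex(gys.index.get_level_values(0)).to_numpy()
               + y_means.reindex(gys.index.get_level_values(1)).to_numpy()
               + s_means.reindex(gys.index.get_level_values(2)).to_numpy()
               - grand)
    ms_g = r * ny * ns * ((g_means - grand) ** 2).sum() / (ng - 1)
    ms_gy = r * ns * (gy_dev ** 2).sum() / ((ng - 1) * (ny - 1))
    ms_gs = r * ny * (gs_dev ** 2).sum() / ((ng - 1) * (ns - 1))
    ms_gys = r * (gys_dev ** 2).sum() / ((ng - 1) * (ny - 1) * (ns - 1))
    return float((ms_g - ms_gy - ms_gs + ms_gys) / ms_g)


# -- GWAS --------------------------------------------------------------------

def gwas_scan(y, vm: VariantMatrix, block=None, maf_min: float = 0.05,
              miss_max: float = 0.2, fdr_alpha: float = 0.001,
              hard_p: float = 1e-10, coding: str = "dosage") -> pd.DataFrame:
    """Single-marker association scan with a block fixed effect.

    Per SNP: value ~ block + SNP, F-tested; missing dosages excluded
    casewise. ``coding="dosage"`` (default) fits the additive dosage
    covariate (1 df); ``coding="factor"`` fits genotype classes as a
    categorical factor (df = classes - 1), in which case the reported
    effect is NaN. Returns a DataFrame with effect, statistic, p, BH
    q-value and the two significance flags. SNPs with fewer than 3
    informative samples get NaN results.
    """
    if coding not in ("dosage", "factor"):
        raise ValueError("coding must be 'dosage' or 'factor'")
    y = np.asarray(y, dtype=float)
    if len(y) != vm.n_samples:
        raise ValueError("phenotype must align with samples")
    keep = (np.nan_to_num(vm.maf(), nan=0.0) >= maf_min) & \
        (vm.missing_fraction() <= miss_max)
    sub = vm.take_variants(np.where(keep)[0])
    if block is None:
        B = np.ones((len(y), 1))
    else:
        B, _ = _one_hot(pd.Series(block).astype(str))
    rank_b = np.linalg.matrix_rank(B)
    Q, _ = np.linalg.qr(B)
    Q = Q[:, :rank_b]

    def residualize(v, q):
        return v - q @ (q.T @ v)

    X = sub.dosage
    eff = np.full(sub.n_variants, np.nan)
    stat = np.full(sub.n_variants, np.nan)
    pval = np.full(sub.n_variants, np.nan)
    if coding == "factor":
        for j in range(sub.n_variants):
            x = X[:, j]
            m = ~np.isnan(x)
            if m.sum() < 3:
                continue
            classes = np.unique(x[m])
            if len(classes) < 2:
                continue
            Bm = B[m]
            Gm = (x[m][:, None] == classes[1:]).astype(float)
            X1 = np.hstack([Bm, Gm])
            r0 = y[m] - Bm @ np.linalg.lstsq(Bm, y[m], rcond=None)[0]
            r1 = y[m] - X1 @ np.linalg.lstsq(X1, y[m], rcond=None)[0]
            df1 = np.linalg.matrix_rank(X1) - np.linalg.matrix_rank(Bm)
            df2 = int(m.sum()) - np.linalg.matrix_rank(X1)
            if df1 < 1 or df2 < 1:
                continue
            F = ((r0 @ r0 - r1 @ r1) / df1) / ((r1 @ r1) / df2)
            stat[j] = F
            pval[j] = sps.f.sf(F, df1, df2)
        return _assemble_gwas(sub, eff, stat, pval, fdr_alpha, hard_p)

    complete = ~np.isnan(X).any(axis=0)
    if complete.any():
        yr = residualize(y, Q)
        Xr = residualize(X[:, complete], Q)
        sxx = (Xr ** 2).sum(axis=0)
        ok = sxx > 0
        df_resid = len(y) - rank_b - 1
        sxy = Xr.T @ yr
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        rss = (yr @ yr) - beta * sxy
        sigma2 = rss / df_resid
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / np.sqrt(sigma2 / np.where(ok, sxx, 1.0))
        idx = np.where(complete)[0]
        eff[idx] = beta
        stat[idx] = t ** 2
        pval[idx] = sps.f.sf(t ** 2, 1, df_resid)
        eff[idx[~ok]] = stat[idx[~ok]] = pval[idx[~ok]] = np.nan
    for j in np.where(~complete)[0]:
        x = X[:, j]
        m = ~np.isnan(x)
        if m.sum() < 3 or np.nanstd(x[m]) == 0:
            continue
        Bm = B[m]
        rb = np.linalg.matrix_rank(Bm)
        Qm, _ = np.linalg.qr(Bm)
        Qm = Qm[:, :rb]
        yr = residualize(y[m], Qm)
        xr = residualize(x[m], Qm)
        sxx = xr @ xr
        dfr = m.sum() - rb - 1
        if sxx == 0 or dfr < 1:
            continue
        beta = (xr @ yr) / sxx
        sigma2 = (yr @ yr - beta * (xr @ yr)) / dfr
        t2 = beta ** 2 * sxx / sigma2 if sigma2 > 0 else np.inf
        eff[j], stat[j] = beta, t2
        pval[j] = sps.f.sf(t2, 1, dfr)

    return _assemble_gwas(sub, eff, stat, pval, fdr_alpha, hard_p)


def _assemble_gwas(sub, eff, stat, pval, fdr_alpha, hard_p):
    res = pd.DataFrame({
        "chrom": sub.chrom, "pos": sub.pos, "effect": eff,
        "stat": stat, "p": pval,
    })
    q = np.full(len(res), np.nan)
    okp = res["p"].notna().to_numpy()
    if okp.any():
        q[okp], _ = bh_fdr(res.loc[okp, "p"].to_numpy(), alpha=fdr_alpha)
    res["q"] = q
    res["significant_fdr"] = res["q"] <= fdr_alpha
    res["significant_hard"] = res["p"] < hard_p
    return res


def bh_fdr(p, alpha: float = 0.001):
    """Benjamini-Hochberg step-up. Returns (q_values, reject_mask)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def qq_calibration(p):
    """Observed vs expected -log10 p quantiles and genomic inflation.

    Expected quantiles use (i - 0.5)/m; the inflation factor is the median
    observed 1-df chi-square statistic over its null median (0.4549).
    """
    p = np.asarray(p, dtype=float)
    if p.size < 10:
        raise ValueError("need >= 10 p-values")
    obs = np.sort(p)
    m = len(obs)
    expected = (np.arange(1, m + 1) - 0.5) / m
    pairs = pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.maximum(obs, 1e-300)),
    })
    chi2 = sps.chi2.isf(np.clip(obs, 1e-300, 1.0), df=1)
    inflation = float(np.median(chi2) / sps.chi2.ppf(0.5, df=1))
    return pairs, inflation
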