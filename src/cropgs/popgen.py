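"""Windowed diversity/differentiation scan and related population genetics.

Implements per-site and per-window estimators of nucleotide diversity
(theta_pi), Watterson's theta, Tajima's D and Hudson's F_ST; the joint
loss-of-diversity / excess-differentiation outlier rule for domestication
scans; LD decay; allele-sharing (p-) distances with a neighbor-joining
tree; and PCA of the dosage matrix.

Conventions: window coordinates are 1-based inclusive; per-bp statistics
divide by the window's effective (non-N) length; F_ST windows aggregate
Hudson's per-site estimator as a ratio of averages; the diversity-ratio
statistic is -log10(pi_cultivated / pi_wild), so 1 marks a tenfold loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import VariantMatrix

__all__ = [
    "site_diversity", "watterson_theta", "tajima_d", "hudson_fst",
    "hudson_fst_components", "neg_log_ratio", "window_scan", "call_outliers",
    "ld_decay", "LDDecayResult", "p_distance_matrix", "nj_tree", "pca",
]


# -- per-site estimators -----------------------------------------------------

def site_diversity(alt_count, total_alleles):
    """Unbiased per-site heterozygosity 2*p*(1-p)*n/(n-1).

    Equals the mean pairwise difference over all pairs of the n sampled
    alleles. Vectorised; sites with fewer than 2 alleles return NaN.
    """
    alt = np.asarray(alt_count, dtype=float)
    tot = np.asarray(total_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / tot
        pi = 2.0 * p * (1.0 - p) * tot / (tot - 1.0)
    return np.where(tot >= 2, pi, np.nan)


def _harmonic(n):
    """a_n = sum_{i=1}^{n} 1/i (n may be an array; lookup-table based)."""
    n = np.asarray(n, dtype=int)
    top = int(n.max()) if n.size else 0
    table = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, top + 1))])
    out = table[np.clip(n, 0, top)]
    return out if out.shape else float(out)


def watterson_theta(S, n_alleles, L):
    """Watterson's estimator per bp: S / (a_{n-1} * L)."""
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    if L <= 0:
        raise ValueError("effective length must be positive")
    a = np.sum(1.0 / np.arange(1, n_alleles))
    return S / (a * L)


def tajima_d(S, pi_sum, n_alleles):
    """Tajima's D from segregating sites, total pairwise diversity and n.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    n = int(n_alleles)
    if n < 2:
        raise ValueError("need at least 2 alleles")
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_sum - S / a1) / np.sqrt(var)


def hudson_fst_components(p1, n1, p2, n2):
    """Hudson per-site numerator and denominator (for ratio-of-averages).

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(p1, n1, p2, n2):
    """Per-site Hudson F_ST estimate; NaN where the denominator is zero."""
    num, den = hudson_fst_components(p1, n1, p2, n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan) if np.ndim(out) else \
        (out if den > 0 else float("nan"))


def neg_log_ratio(pi_cult, pi_wild):
    """-log10(pi_cultivated / pi_wild): 0 = diversity maintained,
    1 = tenfold loss in the cultivated group. Undefined (NaN) when either
    diversity is zero."""
    pi_cult = np.asarray(pi_cult, dtype=float)
    pi_wild = np.asarray(pi_wild, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = -np.log10(pi_cult / pi_wild)
    out = np.where((pi_cult > 0) & (pi_wild > 0), out, np.nan)
    return float(out) if np.ndim(out) == 0 else out


# -- window scan -------------------------------------------------------------

def _pop_site_stats(vm, mask):
    alt = np.nansum(vm.dosage[mask], axis=0)
    tot = 2.0 * (~np.isnan(vm.dosage[mask])).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / tot
    seg = (alt > 0) & (alt < tot)
    pi = np.nan_to_num(site_diversity(alt, tot), nan=0.0)
    # per-site Watterson contribution 1/a_{n-1}, using each site's own n
    inv_a = np.where(tot >= 2, 1.0 / np.maximum(_harmonic(np.maximum(tot - 1, 1)), 1e-300), 0.0)
    return {"alt": alt, "tot": tot, "p": p, "seg": seg, "pi": pi,
            "w_contrib": np.where(seg, inv_a, 0.0)}


def window_scan(vm: VariantMatrix, pop_cult: str = "cultivated",
                pop_wild: str = "wild", window: int = 100_000,
                step: int | None = None,
                effective_lengths: dict | None = None,
                chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Per-window diversity and differentiation statistics.

    Windows of ``window`` bp tile each chromosome (start 1, inclusive
    bounds); a variant at the exact window end belongs to that window.
    For each population: segregating sites S, theta_pi and theta_w per bp
    over the effective length, and Tajima's D. Between populations:
    Hudson F_ST (ratio of averages over the window's sites) and the
    -log10 diversity ratio.

    ``effective_lengths`` optionally maps (chrom, start) -> non-N length;
    the default assumes fully callable windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    if vm.population_labels is None:
        raise ValueError("population labels required")
    m_cult = vm.population_labels == pop_cult
    m_wild = vm.population_labels == pop_wild
    if m_cult.sum() < 2 or m_wild.sum() < 2:
        raise ValueError("need >= 2 samples per population")

    stats = {"cult": _pop_site_stats(vm, m_cult),
             "wild": _pop_site_stats(vm, m_wild)}
    both = (stats["cult"]["tot"] >= 2) & (stats["wild"]["tot"] >= 2)
    fnum, fden = hudson_fst_components(
        stats["cult"]["p"], stats["cult"]["tot"],
        stats["wild"]["p"], stats["wild"]["tot"])
    fnum = np.where(both, fnum, 0.0)
    fden = np.where(both, fden, 0.0)

    rows = []
    for c in pd.unique(vm.chrom):
        sel = vm.chrom == c
        pos = vm.pos[sel]
        idx = np.where(sel)[0]
        length = (chrom_lengths or {}).get(c, int(pos.max()) if pos.size else window)
        start = 1
        while start <= length:
            end = start + window - 1
            lo, hi = np.searchsorted(pos, (start, end + 1))
            sites = idx[lo:hi]
            eff = (effective_lengths or {}).get((c, start), window)
            row = {"chrom": c, "start": start, "end": end,
                   "effective_length": eff, "n_sites": len(sites)}
            for pop in ("cult", "wild"):
                st = stats[pop]
                S = int(st["seg"][sites].sum())
                pi_sum = float(st["pi"][sites].sum())
                row[f"S_{pop}"] = S
                if eff > 0:
                    row[f"theta_pi_{pop}"] = pi_sum / eff
                    row[f"theta_w_{pop}"] = float(st["w_contrib"][sites].sum()) / eff
                else:
                    row[f"theta_pi_{pop}"] = np.nan
                    row[f"theta_w_{pop}"] = np.nan
                tots = st["tot"][sites]
                tots = tots[tots >= 2]
                if S > 0 and tots.size:
                    n_alleles = int(np.median(tots))
                    row[f"tajima_d_{pop}"] = tajima_d(S, pi_sum, max(n_alleles, 2))
                else:
                    row[f"tajima_d_{pop}"] = np.nan
            dsum = float(fden[sites].sum())
            row["fst"] = float(fnum[sites].sum()) / dsum if dsum > 0 else np.nan
            row["neg_log_ratio"] = neg_log_ratio(
                row["theta_pi_cult"], row["theta_pi_wild"])
            rows.append(row)
            start += step
    return pd.DataFrame(rows)


def call_outliers(stats: pd.DataFrame, q: float = 0.95):
    """Joint outlier call: windows in the upper ``q`` empirical quantile of
    BOTH the -log10 diversity ratio and F_ST.

    Quantiles (numpy linear / type-7) are taken over windows where both
    statistics are defined; undefined windows are never flagged. Adjacent
    flagged windows merge into regions. Returns ``(flags, regions)`` where
    ``flags`` is a boolean Series aligned with ``stats`` and ``regions`` a
    DataFrame (chrom, start, end, n_windows, max_neg_log_ratio, max_fst,
    mean_tajima_d_cult).
    """
    defined = stats["neg_log_ratio"].notna() & stats["fst"].notna()
    if defined.sum() < 20:
        raise ValueError("need >= 20 windows with defined statistics")
    thr_nlr = np.quantile(stats.loc[defined, "neg_log_ratio"], q)
    thr_fst = np.quantile(stats.loc[defined, "fst"], q)
    flags = defined & (stats["neg_log_ratio"] >= thr_nlr) & \
        (stats["fst"] >= thr_fst)

    regions = []
    cur = None
    for i in np.where(flags.to_numpy())[0]:
        w = stats.iloc[i]
        if (cur is not None and w["chrom"] == cur["chrom"]
                and w["start"] <= cur["end"] + 1):
            cur["end"] = max(cur["end"], int(w["end"]))
            cur["n_windows"] += 1
            cur["max_neg_log_ratio"] = max(cur["max_neg_log_ratio"],
                                           w["neg_log_ratio"])
            cur["max_fst"] = max(cur["max_fst"], w["fst"])
            cur["_td"].append(w.get("tajima_d_cult", np.nan))
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": w["chrom"], "start": int(w["start"]),
                   "end": int(w["end"]), "n_windows": 1,
                   "max_neg_log_ratio": float(w["neg_log_ratio"]),
                   "max_fst": float(w["fst"]),
                   "_td": [w.get("tajima_d_cult", np.nan)]}
    if cur is not None:
        regions.append(cur)
    for r in regions:
        r["mean_tajima_d_cult"] = float(np.nanmean(r.pop("_td"))) \
            if np.isfinite(r["_td"]).any() else np.nan
    cols = ["chrom", "start", "end", "n_windows", "max_neg_log_ratio",
            "max_fst", "mean_tajima_d_cult"]
    return flags, pd.DataFrame(regions, columns=cols)


# -- LD decay ----------------------------------------------------------------

@dataclass
class LDDecayResult:
    bins: pd.DataFrame          # bin_left, bin_right, center, mean_r2, n_pairs
    decay_distance: float       # bp where mean r2 first drops below threshold
    r2_threshold: float


def ld_decay(vm: VariantMatrix, max_distance: int = 250_000,
             maf_min: float = 0.05, r2_threshold: float = 0.2,
             n_bins: int = 25) -> LDDecayResult:
    """Pairwise r^2 against physical distance, binned, with decay distance.

    r^2 is the squared Pearson correlation of dosages (exact haplotype r^2
    for inbred lines); missing dosages are mean-imputed per site. The decay
    distance is the first linear-interpolated crossing of the binned means
    below ``r2_threshold``, anchored at r^2 = 1 at distance 0.
    """
    keep = np.nan_to_num(vm.maf(), nan=0.0) >= maf_min
    sub = vm.take_variants(np.where(keep)[0])
    if sub.n_variants < 2:
        raise ValueError("need >= 2 SNPs passing the MAF filter")
    X = sub.dosage.copy()
    mu = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.take(mu, np.where(nan)[1])
    X -= X.mean(axis=0)
    ss = (X ** 2).sum(axis=0)

    dists, r2s = [], []
    for c in pd.unique(sub.chrom):
        sel = np.where(sub.chrom == c)[0]
        pos = sub.pos[sel]
        for ii, i in enumerate(sel):
            hi = np.searchsorted(pos, pos[ii] + max_distance, side="right")
            js = sel[ii + 1:hi]
            if js.size == 0 or ss[i] == 0:
                continue
            ok = ss[js] > 0
            js = js[ok]
            if js.size == 0:
                continue
            num = X[:, i] @ X[:, js]
            r2s.append(num ** 2 / (ss[i] * ss[js]))
            dists.append(sub.pos[js] - pos[ii])
    if not dists:
        return LDDecayResult(
            bins=pd.DataFrame(columns=["bin_left", "bin_right", "center",
                                       "mean_r2", "n_pairs"]),
            decay_distance=float("nan"), r2_threshold=r2_threshold)
    dist = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)
    edges = np.linspace(0, max_distance, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.any():
            rows.append({"bin_left": edges[b], "bin_right": edges[b + 1],
                         "center": 0.5 * (edges[b] + edges[b + 1]),
                         "mean_r2": float(r2[m].mean()),
                         "n_pairs": int(m.sum())})
    bins = pd.DataFrame(rows)
    decay = float("nan")
    xs = np.concatenate([[0.0], bins["center"].to_numpy()])
    ys = np.concatenate([[1.0], bins["mean_r2"].to_numpy()])
    for a in range(1, len(xs)):
        if ys[a] < r2_threshold <= ys[a - 1]:
            decay = xs[a - 1] + (ys[a - 1] - r2_threshold) * \
                (xs[a] - xs[a - 1]) / (ys[a - 1] - ys[a])
            break
    return LDDecayResult(bins=bins, decay_distance=decay,
                         r2_threshold=r2_threshold)


# -- distances, tree, PCA ----------------------------------------------------

def p_distance_matrix(vm: VariantMatrix) -> pd.DataFrame:
    """Allele-sharing distance: mean |dosage_i - dosage_j| / 2 over sites
    non-missing in both samples. Symmetric with zero diagonal."""
    if vm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = vm.dosage
    n = vm.n_samples
    D = np.zeros((n, n))
    ok = ~np.isnan(X)
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:])        # NaN propagates
        shared = ok[i] & ok[i + 1:]
        cnt = shared.sum(axis=1)
        if (cnt == 0).any():
            j = i + 1 + int(np.where(cnt == 0)[0][0])
            raise ValueError(
                f"samples {vm.sample_ids[i]} and {vm.sample_ids[j]} share no "
                "called sites")
        d = np.nansum(np.where(shared, diff, 0.0), axis=1) / (2.0 * cnt)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return pd.DataFrame(D, index=vm.sample_ids, columns=vm.sample_ids)


def nj_tree(dist) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string with branch
    lengths (negative estimates clamped to zero)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(dist, pd.DataFrame):
        dm = DistanceMatrix(dist.to_numpy(), ids=[str(i) for i in dist.index])
    else:
        dm = DistanceMatrix(np.asarray(dist))
    if dm.shape[0] < 3:
        raise ValueError("need >= 3 taxa for neighbor joining")
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()


def pca(vm: VariantMatrix, n_components: int = 10):
    """PCA of the column-centered dosage matrix (missing mean-imputed).

    Returns ``(coords, explained)``: sample coordinates (n x k DataFrame)
    and the fraction of total variance per component (non-increasing,
    summing to <= 1).
    """
    if vm.n_samples < 2 or vm.n_variants < 1:
        raise ValueError("need >= 2 samples and >= 1 variant")
    X = vm.dosage.copy()
    mu = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.take(mu, np.where(nan)[1])
    X -= X.mean(axis=0)
    k = min(n_components, *X.shape)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    if total == 0:
        coords = np.zeros((vm.n_samples, k))
        explained = np.zeros(k)
    else:
        coords = U[:, :k] * s[:k]
        explained = s[:k] ** 2 / total
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=vm.sample_ids, columns=cols), explained
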