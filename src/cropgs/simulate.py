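"""Synthetic genotype, phenotype and k-mer data with known truth.

The generators emulate the statistical structure of a crop
domestication/breeding study: a heterozygous wild panel and an inbred
cultivated panel diverged under a Balding-Nichols model, selective-sweep
windows where cultivated diversity is pushed toward fixation, inbred
parental panels (B- and R-lines), hybrids obtained by crossing inbreds,
and multi-environment trial phenotypes with additive + dominance
architecture, GxE and a targeted line-mean heritability. Every generator
is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import KmerHistogram, kmer_histogram
from .variants import VariantMatrix


@dataclass
class EnvParams:
    """Trial-design dimensions and variance components.

    Defaults mirror a two-year, three-stress-regime, two-replication
    testcross trial. ``sigma2_e`` is normally solved from ``target_h2``
    by :func:`simulate_phenotypes`; set it explicitly only with
    ``target_h2=None``.
    """

    n_years: int = 2
    n_stresses: int = 3
    n_reps: int = 2
    sigma2_g: float = 1.0
    sigma2_gy: float = 0.25
    sigma2_gs: float = 0.25
    sigma2_gys: float = 0.25
    sigma2_env: float = 1.0     # year/stress main-effect scale
    sigma2_block: float = 0.25
    sigma2_e: float | None = None
    block_size: int = 50

    @property
    def n_envs(self) -> int:
        return self.n_years * self.n_stresses


@dataclass
class SimTruth:
    """Ground truth shared by the generators.

    allele_freqs / additive_effects / dominance_effects are drawn lazily
    (from ``seed``) when not supplied.
    """

    seed: int = 0
    allele_freqs: np.ndarray | None = None
    fst_target: float = 0.1
    sweep_windows: list = field(default_factory=list)
    sweep_push: float = 0.95
    additive_effects: np.ndarray | None = None
    dominance_effects: np.ndarray | None = None
    n_causal: int = 500
    target_h2: float | None = 0.5
    env_params: EnvParams = field(default_factory=EnvParams)

    def __post_init__(self):
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        if self.target_h2 is not None and not (0 <= self.target_h2 <= 1):
            raise ValueError("target_h2 must be in [0, 1]")
        sw = sorted(tuple(w) for w in self.sweep_windows)
        for (a, b), (c, d) in zip(sw, sw[1:]):
            if c <= b:
                raise ValueError("sweep_windows must be disjoint")
        self.sweep_windows = sw


def _ancestral_freqs(rng, n_loci):
    return rng.uniform(0.05, 0.95, size=n_loci)


def _balding_nichols(rng, p, fst):
    """Draw population frequencies around ancestral p at divergence fst."""
    if fst <= 0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b)


def _positions(rng, n_loci, chrom_length):
    pos = np.sort(rng.choice(np.arange(1, chrom_length + 1),
                             size=n_loci, replace=False))
    return pos


def _alleles(rng, n_loci):
    bases = np.array(list("ACGT"), dtype=object)
    ref = rng.choice(bases, size=n_loci)
    shift = rng.integers(1, 4, size=n_loci)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    return ref, alt


def simulate_populations(truth: SimTruth, n_wild: int = 100,
                         n_cult: int = 100, n_loci: int = 5000,
                         chrom_length: int = 10_000_000,
                         chrom: str = "Pg1",
                         wild_subgroups: int = 1,
                         wild_subgroup_fst: float = 0.15) -> VariantMatrix:
    """Wild (heterozygous, HWE) and cultivated (inbred) panels.

    Population frequencies diverge from shared ancestral frequencies by a
    Balding-Nichols Beta draw at F = ``truth.fst_target``. Inside
    ``truth.sweep_windows`` the cultivated frequencies are pushed toward
    the nearer fixation point with strength ``truth.sweep_push``, producing
    the >=10-fold diversity loss and excess differentiation a domestication
    scan should flag. ``wild_subgroups > 1`` adds within-wild structure.
    """
    if n_wild < 2 or n_cult < 2:
        raise ValueError("need at least 2 samples per population")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(truth.seed)
    p_anc = (truth.allele_freqs if truth.allele_freqs is not None
             else _ancestral_freqs(rng, n_loci))
    p_anc = np.asarray(p_anc, dtype=float)
    if len(p_anc) != n_loci:
        raise ValueError("allele_freqs length must equal n_loci")
    pos = _positions(rng, n_loci, chrom_length)
    ref, alt = _alleles(rng, n_loci)

    p_wild = _balding_nichols(rng, p_anc, truth.fst_target)
    p_cult = _balding_nichols(rng, p_anc, truth.fst_target)

    in_sweep = np.zeros(n_loci, dtype=bool)
    for a, b in truth.sweep_windows:
        in_sweep |= (pos >= a) & (pos <= b)
    if in_sweep.any():
        s = truth.sweep_push
        target = np.round(p_cult[in_sweep])  # nearer fixation point
        p_cult[in_sweep] = (1 - s) * p_cult[in_sweep] + s * target

    if wild_subgroups > 1:
        sizes = np.full(wild_subgroups, n_wild // wild_subgroups)
        sizes[: n_wild % wild_subgroups] += 1
        wild_rows = []
        for sz in sizes:
            p_sub = _balding_nichols(rng, p_wild, wild_subgroup_fst)
            wild_rows.append(rng.binomial(2, p_sub, size=(sz, n_loci)))
        wild = np.vstack(wild_rows).astype(float)
    else:
        wild = rng.binomial(2, p_wild, size=(n_wild, n_loci)).astype(float)
    cult = 2.0 * rng.binomial(1, p_cult, size=(n_cult, n_loci))

    ids = [f"WILD{i:04d}" for i in range(n_wild)] + \
          [f"CULT{i:04d}" for i in range(n_cult)]
    labels = np.array(["wild"] * n_wild + ["cultivated"] * n_cult, dtype=object)
    return VariantMatrix(
        sample_ids=ids, dosage=np.vstack([wild, cult]),
        chrom=np.full(n_loci, chrom, dtype=object), pos=pos,
        ref=ref, alt=alt, population_labels=labels,
    )


def simulate_parent_panel(truth: SimTruth, n_parents: int = 580,
                          n_loci: int = 2000, n_b: int | None = None,
                          chrom_length: int = 10_000_000,
                          chrom: str = "Pg1",
                          group_fst: float = 0.0) -> VariantMatrix:
    """Fully inbred parental panel labeled B (seed side) / R (restorer side).

    Dosages are 0 or 2 with no missing data; locus frequencies follow the
    ancestral frequencies so that sample frequencies sit within binomial
    sampling error of truth. ``group_fst > 0`` diverges the B and R pools
    by a Balding-Nichols draw around the ancestral frequencies, emulating
    separated maintainer/restorer breeding pools (between-pool crosses
    then segregate at more loci, the raw material of heterosis).
    """
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    rng = np.random.default_rng(truth.seed)
    p = (truth.allele_freqs if truth.allele_freqs is not None
         else _ancestral_freqs(rng, n_loci))
    p = np.asarray(p, dtype=float)
    pos = _positions(rng, n_loci, chrom_length)
    ref, alt = _alleles(rng, n_loci)
    if n_b is None:
        n_b = n_parents // 2
    if not (0 <= n_b <= n_parents):
        raise ValueError("n_b must lie in [0, n_parents]")
    if group_fst > 0:
        p_b = _balding_nichols(rng, p, group_fst)
        p_r = _balding_nichols(rng, p, group_fst)
        dosage = np.vstack([
            2.0 * rng.binomial(1, p_b, size=(n_b, n_loci)),
            2.0 * rng.binomial(1, p_r, size=(n_parents - n_b, n_loci)),
        ])
    else:
        dosage = 2.0 * rng.binomial(1, p, size=(n_parents, n_loci))
    labels = np.array(["B"] * n_b + ["R"] * (n_parents - n_b), dtype=object)
    ids = [f"B{i:04d}" for i in range(n_b)] + \
          [f"R{i:04d}" for i in range(n_parents - n_b)]
    return VariantMatrix(sample_ids=ids, dosage=dosage,
                         chrom=np.full(n_loci, chrom, dtype=object),
                         pos=pos, ref=ref, alt=alt, population_labels=labels)


def make_hybrids(parents: VariantMatrix, pairs) -> VariantMatrix:
    """Cross inbred parents: hybrid dosage = mean of parental dosages.

    With inbred parents (dosage 0/2) the hybrid dosage is 0, 1 or 2 and a
    dosage of 1 marks a locus where the parents carry different homozygous
    genotypes (the heterozygosity indicator used for dominance).
    """
    d = parents.dosage
    if not np.isin(d, (0.0, 2.0)).all():
        raise ValueError("parents must be fully inbred (dosage 0/2, no missing)")
    index = {s: i for i, s in enumerate(parents.sample_ids)}
    rows, ids = [], []
    for p1, p2 in pairs:
        if p1 not in index or p2 not in index:
            raise KeyError(f"unknown parent in pair ({p1}, {p2})")
        rows.append((d[index[p1]] + d[index[p2]]) / 2.0)
        ids.append(f"{p1}x{p2}")
    return VariantMatrix(
        sample_ids=ids, dosage=np.vstack(rows) if rows else np.empty((0, parents.n_variants)),
        chrom=parents.chrom, pos=parents.pos, ref=parents.ref, alt=parents.alt,
        population_labels=np.full(len(ids), "hybrid", dtype=object),
    )


def draw_effects(truth: SimTruth, n_loci: int, dominance_ratio: float = 0.0):
    """Per-locus additive (and optional dominance) effects.

    ``truth.n_causal`` loci receive exponential-magnitude, random-sign
    additive effects; the rest are zero. Dominance effects, when requested,
    are exponential-magnitude positive (directional dominance) scaled so
    the dominance variance over causal loci is ``dominance_ratio`` times
    the additive variance.
    """
    rng = np.random.default_rng(truth.seed + 1)
    a = np.zeros(n_loci)
    n_causal = min(truth.n_causal, n_loci)
    idx = rng.choice(n_loci, size=n_causal, replace=False)
    a[idx] = rng.exponential(1.0, size=n_causal) * rng.choice((-1, 1), size=n_causal)
    d = np.zeros(n_loci)
    if dominance_ratio > 0:
        d[idx] = rng.exponential(1.0, size=n_causal)
        d *= np.sqrt(dominance_ratio * np.var(a[idx]) / np.var(d[idx]))
    return a, d


def genetic_values(genotypes: VariantMatrix, a, d=None):
    """True genotypic value: sum (x-1)*a + sum het*d."""
    x = genotypes.dosage
    g = (x - 1.0) @ np.asarray(a)
    if d is not None:
        g = g + (x == 1.0) @ np.asarray(d)
    return g


def simulate_phenotypes(genotypes: VariantMatrix, truth: SimTruth,
                        trait: str = "grain_yield",
                        dominance_ratio: float = 0.0) -> pd.DataFrame:
    """Multi-environment trial records with a targeted line-mean heritability.

    value = mu + genetic value + year/stress main effects + GxY + GxS +
    GxYxS + block + residual, one record per genotype x environment x
    replication, environments being the year x stress grid. Genetic values
    are standardised to variance sigma2_g so the residual variance solved
    from ``truth.target_h2`` via

        h2 = s2_G / (s2_G + s2_GY/y + s2_GS/s + s2_GYS/(ys) + s2_e/(ysr))

    realises the requested heritability in expectation.
    """
    ep = truth.env_params
    rng = np.random.default_rng(truth.seed + 2)
    n = genotypes.n_samples
    p = genotypes.n_variants
    if truth.additive_effects is not None:
        a = np.asarray(truth.additive_effects, dtype=float)
        d = (np.zeros(p) if truth.dominance_effects is None
             else np.asarray(truth.dominance_effects, dtype=float))
    else:
        a, d = draw_effects(truth, p, dominance_ratio)
    g = genetic_values(genotypes, a, d)
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd * np.sqrt(ep.sigma2_g)

    y_, s_, r_ = ep.n_years, ep.n_stresses, ep.n_reps
    if truth.target_h2 is not None:
        if truth.target_h2 == 1.0:
            if ep.sigma2_e not in (None, 0.0):
                raise ValueError("target_h2=1 is inconsistent with sigma2_e>0")
            sigma2_e = 0.0
        elif truth.target_h2 == 0.0:
            raise ValueError("target_h2=0 leaves residual variance undefined")
        else:
            h2 = truth.target_h2
            sigma2_e = y_ * s_ * r_ * (
                ep.sigma2_g * (1 - h2) / h2
                - ep.sigma2_gy / y_ - ep.sigma2_gs / s_
                - ep.sigma2_gys / (y_ * s_)
            )
            if sigma2_e < 0:
                raise ValueError(
                    "target_h2 unreachable: GxE variance already exceeds the "
                    "non-genetic budget; lower the interaction components"
                )
    else:
        sigma2_e = ep.sigma2_e if ep.sigma2_e is not None else 1.0

    mu = 100.0
    year_eff = rng.normal(0, np.sqrt(ep.sigma2_env), size=y_)
    stress_eff = rng.normal(0, np.sqrt(ep.sigma2_env), size=s_)
    gy = rng.normal(0, np.sqrt(ep.sigma2_gy), size=(n, y_))
    gs = rng.normal(0, np.sqrt(ep.sigma2_gs), size=(n, s_))
    gys = rng.normal(0, np.sqrt(ep.sigma2_gys), size=(n, y_, s_))
    n_blocks = max(1, int(np.ceil(n / ep.block_size)))
    block_of = np.arange(n) // ep.block_size

    records = []
    for yi in range(y_):
        for si in range(s_):
            env = f"Y{yi + 1}S{si + 1}"
            for ri in range(r_):
                block_eff = rng.normal(0, np.sqrt(ep.sigma2_block),
                                       size=n_blocks)
                resid = rng.normal(0, np.sqrt(sigma2_e), size=n)
                vals = (mu + g + year_eff[yi] + stress_eff[si]
                        + gy[:, yi] + gs[:, si] + gys[:, yi, si]
                        + block_eff[block_of] + resid)
                for i, gid in enumerate(genotypes.sample_ids):
                    records.append((gid, env, f"{2011 + yi}", f"S{si + 1}",
                                    ri + 1, f"R{ri + 1}B{block_of[i] + 1}",
                                    trait, vals[i]))
    df = pd.DataFrame(records, columns=["genotype", "environment", "year",
                                        "stress", "replication", "block",
                                        "trait", "value"])
    df.attrs["true_genetic_value"] = pd.Series(g, index=genotypes.sample_ids)
    df.attrs["sigma2_e"] = sigma2_e
    return df


def simulate_reads_kmer(genome_length: int, depth: float, k: int = 17,
                        error_free: bool = True, mode: str = "poisson",
                        read_length: int = 100, seed: int = 0) -> KmerHistogram:
    """K-mer depth histogram of error-free shotgun coverage of a random genome.

    ``mode="poisson"`` draws each genomic k-mer's depth ~ Poisson(depth)
    directly (the model under which the genome-size formula is exact);
    ``mode="reads"`` samples literal reads from a random genome and counts
    their k-mers. Sequencing errors are out of scope: ``error_free`` must
    stay True.
    """
    if genome_length <= k:
        raise ValueError("genome_length must exceed k")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not error_free:
        raise NotImplementedError("error simulation is out of scope")
    rng = np.random.default_rng(seed)
    if mode == "poisson":
        n_kmers = genome_length - k + 1
        depths = rng.poisson(depth, size=n_kmers)
        depths = depths[depths > 0]
        counts = np.bincount(depths)
        return KmerHistogram(
            k=k, counts={d: int(c) for d, c in enumerate(counts) if c > 0 and d > 0}
        )
    if mode == "reads":
        genome = "".join(rng.choice(list("ACGT"), size=genome_length))
        n_reads = int(round(depth * genome_length / read_length))
        starts = rng.integers(0, genome_length - read_length + 1, size=n_reads)
        reads = [genome[s:s + read_length] for s in starts]
        return kmer_histogram(reads, k)
    raise ValueError(f"unknown mode {mode!r}")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
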