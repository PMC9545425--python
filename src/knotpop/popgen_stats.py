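"""Diversity and differentiation statistics for population SNP data.

Implements per-site nucleotide diversity, observed heterozygosity and
individual inbreeding coefficients, per-locus Tajima's D, the two-population
Weir-Cockerham F_ST variance-components estimator (ratio of sums across
sites) with locus-bootstrap confidence intervals and label-permutation
p-values, Nei's genetic distances between populations, neighbour-joining
population trees with bootstrap node support, and genotype PCA with
Patterson normalisation.

Resampling is always over RAD loci (150-bp fragments), not individual SNPs,
so linked SNPs on a fragment resample together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .io_core import MISSING, GenotypeMatrix, PopulationMap

# ------------------------------------------------------------------- utilities


def allele_stats(g: GenotypeMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (ALT frequency, called allele count, observed het freq) for ``rows``."""
    sub = g.calls[rows, :]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0).astype(float)
    n_alleles = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        het = np.where(
            n_called > 0,
            np.where(called, sub == 1, False).sum(axis=0) / np.maximum(n_called, 1),
            np.nan,
        )
    return p, n_alleles, het


def locus_groups(g: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Variant indices grouped by RAD locus id (insertion order preserved)."""
    groups: dict[str, list[int]] = {}
    for j, locus in enumerate(g.variant_meta["locus_id"]):
        groups.setdefault(locus, []).append(j)
    return {k: np.asarray(v, dtype=int) for k, v in groups.items()}


# ----------------------------------------------------------------- diversity


def site_pi(g: GenotypeMatrix, pm: PopulationMap, pop: str) -> tuple[pd.Series, float]:
    """Per-site nucleotide diversity pi and its mean across usable sites.

    pi = 2 * n_minor * n_major / (n * (n - 1)) over called alleles; sites with
    fewer than 2 called alleles are excluded.
    """
    rows = pm.indices_for(pop, g)
    p, n, _ = allele_stats(g, rows)
    n_alt = p * n
    n_ref = n - n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * n_alt * n_ref / (n * (n - 1.0))
    pi = np.where(n >= 2, pi, np.nan)
    s = pd.Series(pi, name="pi")
    return s, float(np.nanmean(pi)) if np.isfinite(pi).any() else float("nan")


def heterozygosity_fis(
    g: GenotypeMatrix, pm: PopulationMap, pop: str
) -> tuple[float, pd.Series]:
    """Observed heterozygosity and per-individual inbreeding coefficient F.

    F = (O_hom - E_hom) / (N - E_hom) per individual, with E_hom computed
    from sample allele frequencies with the small-sample correction
    E[hom] = 1 - 2p(1-p) * 2n/(2n-1), restricted to each individual's called
    sites.  Individuals with no called sites are excluded.
    """
    rows = pm.indices_for(pop, g)
    p, n_alleles, _ = allele_stats(g, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_het = 2.0 * p * (1.0 - p) * n_alleles / np.maximum(n_alleles - 1.0, 1e-12)
    e_hom_site = 1.0 - e_het

    fis = {}
    n_het_total = 0
    n_called_total = 0
    for i in rows:
        called = g.calls[i] != MISSING
        usable = called & (n_alleles >= 2)
        n_sites = int(usable.sum())
        if n_sites == 0:
            continue
        o_hom = int((g.calls[i, usable] != 1).sum())
        e_hom = float(e_hom_site[usable].sum())
        denom = n_sites - e_hom
        fis[g.sample_ids[i]] = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else 0.0
        n_het_total += n_sites - o_hom
        n_called_total += n_sites
    h_obs = n_het_total / n_called_total if n_called_total else float("nan")
    return h_obs, pd.Series(fis, name="F_IS")


_TAJIMA_CACHE: dict[int, tuple[float, ...]] = {}


def _tajima_constants(n: int) -> tuple[float, ...]:
    """a1, a2, b1, b2, c1, c2, e1, e2 for n sampled alleles."""
    if n in _TAJIMA_CACHE:
        return _TAJIMA_CACHE[n]
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    out = (a1, a2, b1, b2, c1, c2, e1, e2)
    _TAJIMA_CACHE[n] = out
    return out


def tajimas_d(g: GenotypeMatrix, pm: PopulationMap, pop: str) -> pd.Series:
    """Per-locus Tajima's D within a population.

    Loci with no segregating site in the population are undefined and
    excluded.  The allele sample size per locus is the rounded mean number of
    called alleles over its segregating sites (constant when data are
    complete); loci with n < 4 alleles are excluded.
    """
    rows = pm.indices_for(pop, g)
    p, n_alleles, _ = allele_stats(g, rows)
    n_alt = p * n_alleles
    n_ref = n_alleles - n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = 2.0 * n_alt * n_ref / (n_alleles * (n_alleles - 1.0))
    seg = (n_alt > 0) & (n_ref > 0) & (n_alleles >= 2)

    values = {}
    for locus, idx in locus_groups(g).items():
        sidx = idx[seg[idx]]
        s = len(sidx)
        if s == 0:
            continue
        n = int(round(float(np.mean(n_alleles[sidx]))))
        if n < 4:
            continue
        a1, _, _, _, _, _, e1, e2 = _tajima_constants(n)
        pi_sum = float(np.nansum(pi_site[sidx]))
        var = e1 * s + e2 * s * (s - 1.0)
        if var <= 0:
            continue
        values[locus] = (pi_sum - s / a1) / np.sqrt(var)
    return pd.Series(values, name="tajimas_d")


@dataclass
class PopulationStats:
    """Per-population diversity summary."""

    population: str
    mean_pi: float
    h_obs: float
    fis: pd.Series
    tajimas_d: pd.Series

    @property
    def mean_fis(self) -> float:
        return float(self.fis.mean()) if len(self.fis) else float("nan")

    @property
    def mean_tajimas_d(self) -> float:
        return float(self.tajimas_d.mean()) if len(self.tajimas_d) else float("nan")


def population_stats(g: GenotypeMatrix, pm: PopulationMap) -> dict[str, PopulationStats]:
    out = {}
    for pop in pm.populations:
        _, mean_pi = site_pi(g, pm, pop)
        h_obs, fis = heterozygosity_fis(g, pm, pop)
        d = tajimas_d(g, pm, pop)
        out[pop] = PopulationStats(pop, mean_pi, h_obs, fis, d)
    return out


# ------------------------------------------------------------- differentiation


def wc_components_from_stats(
    pa: np.ndarray,
    na2: np.ndarray,
    ha: np.ndarray,
    pb: np.ndarray,
    nb2: np.ndarray,
    hb: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for two populations,
    from per-population (ALT freq, called allele count, observed het freq).

    Sites monomorphic across both populations (or with a population having
    fewer than 2 called genotypes) contribute zero to every component.
    """
    n_a = na2 / 2.0  # diploid counts
    n_b = nb2 / 2.0
    ok = (n_a >= 2) & (n_b >= 2)
    r = 2.0
    nbar = (n_a + n_b) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1.0)
        pbar = (n_a * pa + n_b * pb) / (r * nbar)
        s2 = (n_a * (pa - pbar) ** 2 + n_b * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n_a * ha + n_b * hb) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    poly = ok & (pbar > 0) & (pbar < 1)
    zero = ~poly
    for arr in (a, b, c):
        arr[zero] = 0.0
        arr[np.isnan(arr)] = 0.0
    return a, b, c


def wc_components(
    g: GenotypeMatrix, rows_a: np.ndarray, rows_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pa, na2, ha = allele_stats(g, rows_a)
    pb, nb2, hb = allele_stats(g, rows_b)
    return wc_components_from_stats(pa, na2, ha, pb, nb2, hb)


def wc_fst(g: GenotypeMatrix, pm: PopulationMap, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta: sum(a) / sum(a + b + c) across sites."""
    rows_a = pm.indices_for(pop_a, g)
    rows_b = pm.indices_for(pop_b, g)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("need >= 2 samples per population")
    a, b, c = wc_components(g, rows_a, rows_b)
    denom = (a + b + c).sum()
    return float(a.sum() / denom) if denom != 0 else float("nan")


def fst_bootstrap_ci(
    g: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str,
    pop_b: str,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI for theta from resampling RAD loci with replacement."""
    rng = rng if rng is not None else np.random.default_rng()
    rows_a = pm.indices_for(pop_a, g)
    rows_b = pm.indices_for(pop_b, g)
    a, b, c = wc_components(g, rows_a, rows_b)
    groups = list(locus_groups(g).values())
    a_loc = np.array([a[idx].sum() for idx in groups])
    abc_loc = np.array([(a[idx] + b[idx] + c[idx]).sum() for idx in groups])
    n_loci = len(groups)
    thetas = np.empty(n_boot)
    for k in range(n_boot):
        pick = rng.integers(0, n_loci, size=n_loci)
        denom = abc_loc[pick].sum()
        thetas[k] = a_loc[pick].sum() / denom if denom != 0 else np.nan
    lo, hi = np.nanpercentile(thetas, [2.5, 97.5])
    return float(lo), float(hi)


def fst_permutation_p(
    g: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value: p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1)."""
    rng = rng if rng is not None else np.random.default_rng()
    rows_a = pm.indices_for(pop_a, g)
    rows_b = pm.indices_for(pop_b, g)
    pooled = np.concatenate([rows_a, rows_b])
    na = len(rows_a)
    a, b, c = wc_components(g, rows_a, rows_b)
    denom = (a + b + c).sum()
    theta_obs = a.sum() / denom if denom != 0 else 0.0
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        pa, pb, pc = wc_components(g, perm[:na], perm[na:])
        d = (pa + pb + pc).sum()
        theta = pa.sum() / d if d != 0 else 0.0
        if theta >= theta_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    theta: float
    ci_low: float
    ci_high: float
    p_value: float


def pairwise_fst_table(
    g: GenotypeMatrix,
    pm: PopulationMap,
    n_boot: int = 500,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """All pairwise theta estimates with bootstrap CIs and permutation p-values."""
    rng = rng if rng is not None else np.random.default_rng()
    records = []
    pops = pm.populations
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            if min(len(pm.indices_for(a, g)), len(pm.indices_for(b, g))) < 2:
                continue  # differentiation undefined for singleton populations
            theta = wc_fst(g, pm, a, b)
            lo, hi = fst_bootstrap_ci(g, pm, a, b, n_boot, rng)
            p = fst_permutation_p(g, pm, a, b, n_perm, rng)
            records.append(FstResult(a, b, theta, lo, hi, p).__dict__)
    return pd.DataFrame(records)


# -------------------------------------------------------------- Nei distances


def _pop_frequencies(g: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """ALT-allele frequencies per population; missing data are replaced by the
    population mean allele count (i.e., frequencies are computed over called
    alleles only, the mean-imputation equivalent for frequency estimates)."""
    freqs = {}
    for pop in pm.populations:
        p, _, _ = allele_stats(g, pm.indices_for(pop, g))
        freqs[pop] = p
    return pd.DataFrame(freqs)


def nei_distance(
    g: GenotypeMatrix, pm: PopulationMap, method: str = "minimum"
) -> pd.DataFrame:
    """Population x population Nei genetic distance matrix.

    ``method='minimum'`` (default): Dm = mean over sites of
    (Jx + Jy)/2 - Jxy with Jx = sum p^2 over the two alleles.
    ``method='standard'``: Nei's 1972 distance
    D = -ln( sum Jxy / sqrt(sum Jx * sum Jy) ) aggregated over sites.
    """
    if method not in ("minimum", "standard"):
        raise ValueError("method must be 'minimum' or 'standard'")
    freqs = _pop_frequencies(g, pm)
    pops = pm.populations
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            px = freqs[pops[i]].to_numpy()
            py = freqs[pops[j]].to_numpy()
            ok = np.isfinite(px) & np.isfinite(py)
            px, py = px[ok], py[ok]
            jx = px**2 + (1 - px) ** 2
            jy = py**2 + (1 - py) ** 2
            jxy = px * py + (1 - px) * (1 - py)
            if method == "minimum":
                val = float(np.mean((jx + jy) / 2.0 - jxy))
            else:
                denom = np.sqrt(jx.sum() * jy.sum())
                val = float(-np.log(jxy.sum() / denom)) if denom > 0 else np.nan
            d[i, j] = d[j, i] = max(val, 0.0)
    return pd.DataFrame(d, index=pops, columns=pops)


# ------------------------------------------------------------------- NJ trees


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbour joining on a population distance matrix."""
    if len(d) < 3:
        raise ValueError("need at least 3 taxa for an NJ tree")
    dm = DistanceMatrix(d.to_numpy(), ids=list(d.index))
    return nj(dm)


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, canonicalised to the smaller side
    (ties: lexicographic)."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (
            len(side) == len(other) and sorted(side) < sorted(other)
        ):
            splits.add(side)
        else:
            splits.add(other)
    return splits


def nj_bootstrap(
    g: GenotypeMatrix,
    pm: PopulationMap,
    n_boot: int = 1000,
    method: str = "minimum",
    rng: np.random.Generator | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree on the full data plus bootstrap support (%) per bipartition.

    Bootstrap replicates resample RAD loci with replacement, recompute the Nei
    distance matrix and the NJ tree, and count each split of the full-data
    tree across replicates.
    """
    rng = rng if rng is not None else np.random.default_rng()
    taxa = frozenset(pm.populations)
    tree = nj_tree(nei_distance(g, pm, method))
    target = _bipartitions(tree, taxa)
    counts = {split: 0 for split in target}
    groups = list(locus_groups(g).values())
    n_loci = len(groups)
    for _ in range(n_boot):
        pick = rng.integers(0, n_loci, size=n_loci)
        idx = np.concatenate([groups[k] for k in pick])
        rep = g.take_variants(idx)
        try:
            rep_tree = nj_tree(nei_distance(rep, pm, method))
        except ValueError:
            continue
        rep_splits = _bipartitions(rep_tree, taxa)
        for split in target & rep_splits:
            counts[split] += 1
    support = {split: 100.0 * c / n_boot for split, c in counts.items()}
    return tree, support


# ------------------------------------------------------------------------- PCA


@dataclass
class PcaResult:
    """Per-sample scores on the top axes plus explained-variance fractions."""

    scores: pd.DataFrame
    explained: np.ndarray  # full spectrum, non-increasing, sums to 1

    def explained_by(self, k: int) -> float:
        return float(self.explained[:k].sum())


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Genotype PCA with Patterson normalisation.

    Each variant is centred at its mean dosage and scaled by
    sqrt(p(1-p)) with p the sample ALT frequency; missing cells are
    mean-imputed (zero after centring); monomorphic variants are dropped.
    Scores come from eigendecomposition of the sample x sample covariance.
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise ValueError("need >= 2 samples and >= 2 variants")
    called = g.called
    alt = np.where(called, g.calls, 0).sum(axis=0).astype(float)
    tot = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    x = g.calls[:, keep].astype(float)
    pk = p[keep]
    x[g.calls[:, keep] == MISSING] = np.nan
    x = (x - 2.0 * pk) / np.sqrt(pk * (1.0 - pk))
    x = np.nan_to_num(x, nan=0.0)

    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    explained = evals / total if total > 0 else evals
    k = min(n_components, len(evals))
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(pd.DataFrame(scores, index=g.sample_ids, columns=cols), explained)
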