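"""Fixed summary-statistic vectors for observed and simulated SNP datasets.

The schema is determined by (populations, trios): per population the
proportion of monomorphic loci and the mean/variance across loci of gene
diversity; per population pair the mean/variance of per-locus Weir-Cockerham
F_ST, the mean Nei minimum distance, and the proportion of loci monomorphic
in the pooled pair; per admixture trio (target | source1, source2) the
mean/variance of a per-locus least-squares admixture coefficient.  Linear
discriminant axes fitted on a reference table can be appended as additional
summaries for scenario choice.

Degenerate cells have defined fallbacks so vectors never contain NaN: a pair
with zero F_ST-informative loci reports mean 0 / variance 0; a trio whose
sources never differ reports the symmetric null 0.5 / variance 0.

Gene diversity per locus is the unbiased expected heterozygosity
2*p*(1-p)*n/(n-1) over called alleles, averaged over the locus's sites.
Variances are population variances (ddof 0) so single-locus inputs stay
defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix, PopulationMap
from .popgen_stats import allele_stats, wc_components_from_stats


def summary_names(
    populations: list[str], trios: list[tuple[str, str, str]]
) -> list[str]:
    """Deterministic name -> position schema for a summary vector."""
    names = []
    for p in populations:
        names += [f"mono_{p}", f"gd_mean_{p}", f"gd_var_{p}"]
    for i in range(len(populations)):
        for j in range(i + 1, len(populations)):
            a, b = populations[i], populations[j]
            names += [
                f"fst_mean_{a}_{b}",
                f"fst_var_{a}_{b}",
                f"nei_{a}_{b}",
                f"mono_pair_{a}_{b}",
            ]
    for t, s1, s2 in trios:
        names += [f"adm_mean_{t}_{s1}_{s2}", f"adm_var_{t}_{s1}_{s2}"]
    return names


def _locus_starts(g: GenotypeMatrix) -> np.ndarray:
    codes, _ = pd.factorize(g.variant_meta["locus_id"], sort=False)
    if len(codes) and (np.diff(codes) < 0).any():
        raise ValueError("locus_id blocks must be contiguous in variant order")
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    return starts


def _locus_sum(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(x, starts) if len(x) else np.empty(0)


def summarize(
    g: GenotypeMatrix,
    pm: PopulationMap,
    trios: list[tuple[str, str, str]] | None = None,
) -> dict[str, float]:
    """Compute the named summary vector for a dataset.

    Invariant to sample order and to allele-polarity flips applied
    consistently within a locus.
    """
    trios = trios or []
    pops = pm.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for trio in trios:
        for label in trio:
            if label not in pops:
                raise ValueError(f"trio references unknown population {label!r}")

    starts = _locus_starts(g)
    n_loci = len(starts)
    stats = {}
    for pop in pops:
        rows = pm.indices_for(pop, g)
        if len(rows) == 0:
            raise ValueError(f"population {pop!r} absent from the genotype matrix")
        stats[pop] = allele_stats(g, rows)

    out: dict[str, float] = {}
    seg_by_pop = {}
    for pop in pops:
        p, n2, _ = stats[pop]
        defined = n2 >= 2
        seg = defined & (p > 0) & (p < 1)
        seg_by_pop[pop] = seg
        with np.errstate(invalid="ignore", divide="ignore"):
            gd = np.where(defined, 2.0 * p * (1 - p) * n2 / np.maximum(n2 - 1.0, 1e-12), 0.0)
        n_def = _locus_sum(defined.astype(float), starts)
        has_data = n_def > 0
        gd_locus = np.where(has_data, _locus_sum(gd, starts) / np.maximum(n_def, 1.0), 0.0)
        seg_locus = _locus_sum(seg.astype(float), starts) > 0
        n_data = max(int(has_data.sum()), 1)
        out[f"mono_{pop}"] = float((has_data & ~seg_locus).sum() / n_data)
        out[f"gd_mean_{pop}"] = float(gd_locus[has_data].mean()) if has_data.any() else 0.0
        out[f"gd_var_{pop}"] = float(gd_locus[has_data].var()) if has_data.any() else 0.0

    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            pa, na2, ha = stats[a]
            pb, nb2, hb = stats[b]
            ca, cb, cc = wc_components_from_stats(pa, na2, ha, pb, nb2, hb)
            a_loc = _locus_sum(ca, starts)
            d_loc = _locus_sum(ca + cb + cc, starts)
            informative = np.abs(d_loc) > 1e-12
            if informative.any():
                fst_loc = a_loc[informative] / d_loc[informative]
                out[f"fst_mean_{a}_{b}"] = float(fst_loc.mean())
                out[f"fst_var_{a}_{b}"] = float(fst_loc.var())
            else:
                out[f"fst_mean_{a}_{b}"] = 0.0
                out[f"fst_var_{a}_{b}"] = 0.0
            # Nei minimum distance, mean over sites defined in both pops
            both = (na2 >= 2) & (nb2 >= 2)
            if both.any():
                px, py = pa[both], pb[both]
                jx = px**2 + (1 - px) ** 2
                jy = py**2 + (1 - py) ** 2
                jxy = px * py + (1 - px) * (1 - py)
                out[f"nei_{a}_{b}"] = float(np.mean((jx + jy) / 2.0 - jxy))
            else:
                out[f"nei_{a}_{b}"] = 0.0
            # pooled-pair monomorphic loci
            with np.errstate(invalid="ignore"):
                alt = np.nan_to_num(pa * na2) + np.nan_to_num(pb * nb2)
                tot = np.where(na2 >= 2, na2, 0) + np.where(nb2 >= 2, nb2, 0)
            seg_pool = (alt > 0) & (alt < tot) & (tot > 0)
            has = _locus_sum((tot > 0).astype(float), starts) > 0
            seg_l = _locus_sum(seg_pool.astype(float), starts) > 0
            out[f"mono_pair_{a}_{b}"] = float(
                (has & ~seg_l).sum() / max(int(has.sum()), 1)
            )

    for t, s1, s2 in trios:
        pt, nt2, _ = stats[t]
        p1, n12, _ = stats[s1]
        p2, n22, _ = stats[s2]
        ok = (nt2 >= 2) & (n12 >= 2) & (n22 >= 2)
        d = np.where(ok, p1 - p2, 0.0)
        num = np.where(ok, d * (pt - p2), 0.0)
        w_loc = _locus_sum(d * d, starts)
        num_loc = _locus_sum(num, starts)
        informative = w_loc > 1e-12
        if informative.any():
            coef = np.clip(num_loc[informative] / w_loc[informative], 0.0, 1.0)
            out[f"adm_mean_{t}_{s1}_{s2}"] = float(coef.mean())
            out[f"adm_var_{t}_{s1}_{s2}"] = float(coef.var())
        else:
            out[f"adm_mean_{t}_{s1}_{s2}"] = 0.5
            out[f"adm_var_{t}_{s1}_{s2}"] = 0.0

    expected = summary_names(pops, trios)
    return {name: out[name] for name in expected}


# ------------------------------------------------------------------------- LDA


@dataclass
class LdaProjector:
    """Standardise-then-project mapping onto linear discriminant axes.

    Fitted on the reference table only (never on the observed vector) with a
    pooled within-class covariance stabilised by a small ridge (shrinkage).
    """

    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray
    lda: object  # fitted sklearn LinearDiscriminantAnalysis
    n_axes: int

    def transform(self, values: pd.DataFrame | pd.Series) -> np.ndarray:
        if isinstance(values, pd.Series):
            x = values[self.columns].to_numpy(dtype=float)[None, :]
        else:
            x = values[self.columns].to_numpy(dtype=float)
        z = (x - self.mean) / self.scale
        return np.asarray(self.lda.transform(z))[:, : self.n_axes]

    @property
    def axis_names(self) -> list[str]:
        return [f"lda_{i + 1}" for i in range(self.n_axes)]


def fit_lda(table: pd.DataFrame, summary_cols: list[str], shrinkage: float = 1e-3) -> LdaProjector:
    """Fit discriminant axes separating scenarios in summary space.

    Returns ``n_scenarios - 1`` axes.  Constant summaries are kept (their
    scale is set to 1) so the schema stays fixed.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    y = table["scenario"].to_numpy()
    k = len(np.unique(y))
    if k < 2:
        raise ValueError("LDA needs at least two scenarios")
    x = table[summary_cols].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - mean) / scale
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
    lda.fit(z, y)
    return LdaProjector(list(summary_cols), mean, scale, lda, n_axes=k - 1)


def apply_lda(projector: LdaProjector, vector: pd.Series) -> pd.Series:
    """Append the projector's discriminant scores to a summary vector."""
    axes = projector.transform(vector)[0]
    extra = pd.Series(axes, index=projector.axis_names)
    return pd.concat([vector, extra])
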