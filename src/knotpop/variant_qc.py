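"""SNP and sample quality-control chain for RAD-seq genotype matrices.

The chain mirrors standard reduced-representation SNP QC: per-variant call
rate, minor-allele count, indel removal, failed samples, per-population
Hardy-Weinberg exact tests, sliding-window LD pruning, per-sample
missingness, and relatedness resolution via the PI-HAT method-of-moments
identity-by-descent estimator.  Every stage records exact before/after
bookkeeping in a :class:`QcReport`.

Threshold semantics follow the literal filter statements: "called in <80%"
and "allele count <10" remove strictly below; ">25% missing" and
"PI-HAT >0.20" remove strictly above.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, PopulationMap

# ----------------------------------------------------------------- bookkeeping


@dataclass
class QcStage:
    """Bookkeeping for one filtering stage (before - removed = after)."""

    name: str
    n_variants_before: int
    n_variants_after: int
    n_samples_before: int
    n_samples_after: int
    params: dict = field(default_factory=dict)

    @property
    def n_removed_variants(self) -> int:
        return self.n_variants_before - self.n_variants_after

    @property
    def n_removed_samples(self) -> int:
        return self.n_samples_before - self.n_samples_after

    def validate(self) -> None:
        if self.n_variants_after > self.n_variants_before:
            raise ValueError(f"stage {self.name}: variants increased")
        if self.n_samples_after > self.n_samples_before:
            raise ValueError(f"stage {self.name}: samples increased")


@dataclass
class QcReport:
    """Ordered stage records; chained stages telescope (initial -> final)."""

    stages: list[QcStage] = field(default_factory=list)

    def add(self, stage: QcStage) -> None:
        stage.validate()
        if self.stages:
            prev = self.stages[-1]
            if (
                stage.n_variants_before != prev.n_variants_after
                or stage.n_samples_before != prev.n_samples_after
            ):
                raise ValueError(
                    f"stage {stage.name} does not chain from {prev.name}"
                )
        self.stages.append(stage)

    def validate(self) -> None:
        for st in self.stages:
            st.validate()
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if (
                nxt.n_variants_before != prev.n_variants_after
                or nxt.n_samples_before != prev.n_samples_after
            ):
                raise ValueError(f"stages {prev.name} -> {nxt.name} do not chain")

    @property
    def final_variants(self) -> int:
        return self.stages[-1].n_variants_after

    @property
    def final_samples(self) -> int:
        return self.stages[-1].n_samples_after

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": st.name,
                    "n_variants_before": st.n_variants_before,
                    "n_variants_removed": st.n_removed_variants,
                    "n_variants_after": st.n_variants_after,
                    "n_samples_before": st.n_samples_before,
                    "n_samples_removed": st.n_removed_samples,
                    "n_samples_after": st.n_samples_after,
                    "params": json.dumps(st.params, sort_keys=True),
                }
                for st in self.stages
            ]
        )

    def to_json(self) -> str:
        return self.to_frame().to_json(orient="records", indent=2)


def _stage(name: str, before: GenotypeMatrix, after: GenotypeMatrix, **params) -> QcStage:
    return QcStage(
        name,
        before.n_variants,
        after.n_variants,
        before.n_samples,
        after.n_samples,
        params,
    )


# --------------------------------------------------------------- variant-level


def filter_call_rate(g: GenotypeMatrix, min_rate: float) -> tuple[GenotypeMatrix, QcStage]:
    """Remove variants called in strictly less than ``min_rate`` of samples."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    rate = g.called.mean(axis=0) if g.n_samples else np.zeros(g.n_variants)
    out = g.take_variants(rate >= min_rate)
    return out, _stage("call_rate", g, out, min_rate=min_rate)


def minor_allele_counts(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor-allele count over called genotypes."""
    called = g.called
    alt = np.where(called, g.calls, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return np.minimum(alt, total - alt)


def filter_mac(g: GenotypeMatrix, min_count: int) -> tuple[GenotypeMatrix, QcStage]:
    """Remove variants whose minor-allele count is strictly below ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    mac = minor_allele_counts(g)
    out = g.take_variants(mac >= min_count)
    return out, _stage("mac", g, out, min_count=min_count)


def drop_indels(g: GenotypeMatrix) -> tuple[GenotypeMatrix, QcStage]:
    keep = ~g.variant_meta["is_indel"].to_numpy(dtype=bool)
    out = g.take_variants(keep)
    return out, _stage("indels", g, out)


# ------------------------------------------------------------------ HWE filter


@lru_cache(maxsize=65536)
def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (probability-mass ordering).

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.  Monomorphic input returns p = 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # P(het = h | n, n_rare) over h with h ≡ n_rare (mod 2)
    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logprobs = {}
    lg = math.lgamma
    for h in hets:
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        # log multinomial coefficient * 2^h / C(2n, n_rare)
        logprobs[h] = (
            lg(n + 1)
            - lg(rare_hom + 1)
            - lg(h + 1)
            - lg(com_hom + 1)
            + h * math.log(2)
            + lg(n_rare + 1)
            + lg(2 * n - n_rare + 1)
            - lg(2 * n + 1)
        )
    mx = max(logprobs.values())
    probs = {h: math.exp(lp - mx) for h, lp in logprobs.items()}
    z = sum(probs.values())
    p_obs = probs[n_het] / z
    p = sum(v / z for v in probs.values() if v / z <= p_obs * (1 + 1e-12))
    return min(p, 1.0)


def genotype_counts(g: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """(n_variants, 3) counts of hom-ref / het / hom-alt among ``rows``."""
    sub = g.calls[rows, :]
    return np.stack([(sub == d).sum(axis=0) for d in (0, 1, 2)], axis=1)


def hwe_filter(
    g: GenotypeMatrix,
    pm: PopulationMap,
    alpha: float = 0.05,
    min_pops: int = 6,
) -> tuple[GenotypeMatrix, QcStage]:
    """Remove variants deviating from HWE (p < alpha) in >= ``min_pops`` populations.

    Populations with fewer than 2 called genotypes at a variant contribute
    "no deviation" there.
    """
    if min_pops > len(pm.populations):
        raise ValueError("min_pops exceeds number of populations")
    n_dev = np.zeros(g.n_variants, dtype=int)
    for pop in pm.populations:
        rows = pm.indices_for(pop, g)
        counts = genotype_counts(g, rows)
        for j in range(g.n_variants):
            aa, ab, bb = (int(c) for c in counts[j])
            if aa + ab + bb < 2:
                continue
            if hwe_exact_test(aa, ab, bb) < alpha:
                n_dev[j] += 1
    out = g.take_variants(n_dev < min_pops)
    return out, _stage("hwe", g, out, alpha=alpha, min_pops=min_pops)


# ------------------------------------------------------------------ LD pruning


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete genotypes."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xi = x[ok].astype(float)
    yi = y[ok].astype(float)
    sx = xi.std()
    sy = yi.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xi - xi.mean()) * (yi - yi.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.20,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, QcStage]:
    """Greedy sliding-window LD pruning on genotype correlation.

    Within each window of ``window`` consecutive SNPs (advancing by ``step``),
    while any retained pair has r^2 > ``r2_max``, the member with the lower
    call rate (ties: higher index) is removed.  The retained set therefore
    contains no within-window pair above the threshold.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if window < 2:
        raise ValueError("window must be >= 2")
    keep = np.ones(g.n_variants, dtype=bool)
    call_rate = g.called.mean(axis=0)
    start = 0
    while start < g.n_variants:
        idx = [j for j in range(start, min(start + window, g.n_variants)) if keep[j]]
        changed = True
        while changed:
            changed = False
            worst = None  # (r2, pair)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    ja, jb = idx[a], idx[b]
                    r2 = _pairwise_r2(g.calls[:, ja], g.calls[:, jb])
                    if r2 > r2_max and (worst is None or r2 > worst[0]):
                        worst = (r2, ja, jb)
            if worst is not None:
                _, ja, jb = worst
                if call_rate[ja] < call_rate[jb]:
                    drop = ja
                elif call_rate[jb] < call_rate[ja]:
                    drop = jb
                else:
                    drop = max(ja, jb)
                keep[drop] = False
                idx.remove(drop)
                changed = True
        if start + window >= g.n_variants:
            break
        start += step
    out = g.take_variants(keep)
    return out, _stage("ld_prune", g, out, r2_max=r2_max, window=window, step=step)


# ---------------------------------------------------------------- sample-level


def individual_missingness(g: GenotypeMatrix) -> pd.Series:
    """Per-sample fraction of missing calls."""
    frac = 1.0 - g.called.mean(axis=1) if g.n_variants else np.zeros(g.n_samples)
    return pd.Series(frac, index=g.sample_ids, name="missing_fraction")


def drop_failed_samples(
    g: GenotypeMatrix, max_missing: float
) -> tuple[GenotypeMatrix, QcStage]:
    """Remove samples with missingness strictly above ``max_missing``."""
    miss = individual_missingness(g)
    out = g.take_samples((miss <= max_missing).to_numpy())
    return out, _stage("failed_samples", g, out, max_missing=max_missing)


def drop_samples(g: GenotypeMatrix, max_missing: float) -> tuple[GenotypeMatrix, QcStage]:
    miss = individual_missingness(g)
    out = g.take_samples((miss <= max_missing).to_numpy())
    return out, _stage("missingness", g, out, max_missing=max_missing)


# ------------------------------------------------------------------ relatedness


@dataclass
class RelatednessMatrix:
    """Symmetric sample x sample PI-HAT matrix with low-confidence flags."""

    sample_ids: list[str]
    pihat: np.ndarray
    low_confidence: np.ndarray  # pairs with <50 co-called variants

    def pairs_above(self, threshold: float) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.pihat[i, j] > threshold:
                    out.append((self.sample_ids[i], self.sample_ids[j], float(self.pihat[i, j])))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pihat, index=self.sample_ids, columns=self.sample_ids)


def pihat(g: GenotypeMatrix, min_pair_variants: int = 50) -> RelatednessMatrix:
    """Method-of-moments identity-by-descent PI-HAT for every sample pair.

    Allele frequencies are estimated from the full retained sample.  For each
    pair, observed IBS0/1/2 counts over co-called variants are matched to
    their expectations under IBD states 0/1/2, solving for P(IBD=k) with
    truncation to the probability simplex; PI-HAT = P2 + P1/2.
    """
    called = g.called
    alt = np.where(called, g.calls, 0).sum(axis=0).astype(float)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    q = 1.0 - p
    # per-variant P(IBS=s | IBD=k); IBD2 => IBS2 always
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p * q
    e1_ibs2 = p**2 + q**2

    n = g.n_samples
    mat = np.zeros((n, n))
    lowconf = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(mat, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[i] & called[j]
            m = int(ok.sum())
            if m < min_pair_variants:
                lowconf[i, j] = lowconf[j, i] = True
            if m == 0:
                continue
            diff = np.abs(g.calls[i, ok].astype(int) - g.calls[j, ok].astype(int))
            # IBS2: same genotype; IBS1: differ by one allele; IBS0: opposite homs
            n_ibs0 = int((diff == 2).sum())
            n_ibs1 = int((diff == 1).sum())
            n_ibs2 = m - n_ibs0 - n_ibs1
            s0 = e0_ibs0[ok].sum()
            p0 = n_ibs0 / s0 if s0 > 0 else 0.0
            s1 = e1_ibs1[ok].sum()
            p1 = (n_ibs1 - p0 * e0_ibs1[ok].sum()) / s1 if s1 > 0 else 0.0
            p2 = (n_ibs2 - p0 * e0_ibs2[ok].sum() - p1 * e1_ibs2[ok].sum()) / m
            # truncate to the simplex
            probs = np.clip([p0, p1, p2], 0.0, None)
            total = probs.sum()
            probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
            ph = float(np.clip(probs[2] + 0.5 * probs[1], 0.0, 1.0))
            mat[i, j] = mat[j, i] = ph
    return RelatednessMatrix(list(g.sample_ids), mat, lowconf | lowconf.T)


def resolve_related(
    rm: RelatednessMatrix,
    threshold: float = 0.20,
    missingness: pd.Series | None = None,
) -> set[str]:
    """Greedy removal set resolving all pairs with PI-HAT > threshold.

    Iteratively removes the sample participating in the most offending pairs;
    ties go to higher missingness, then lexicographically smaller id.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if missingness is None:
        missingness = pd.Series(0.0, index=rm.sample_ids)
    edges = {(a, b) for a, b, _ in rm.pairs_above(threshold)}
    removed: set[str] = set()
    while edges:
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        victim = sorted(
            degree,
            key=lambda s: (-degree[s], -float(missingness.get(s, 0.0)), s),
        )[0]
        removed.add(victim)
        edges = {(a, b) for a, b in edges if victim not in (a, b)}
    return removed


# ------------------------------------------------------------------- full chain

DEFAULT_QC_CONFIG = {
    "min_call_rate": 0.80,
    "min_mac": 10,
    "failed_sample_max_missing": 0.90,
    "hwe_alpha": 0.05,
    "hwe_min_pops": 6,
    "ld_r2_max": 0.20,
    "ld_window": 50,
    "ld_step": 5,
    "max_missing": 0.25,
    "pihat_threshold": 0.20,
}


def run_qc(
    g: GenotypeMatrix,
    pm: PopulationMap,
    config: dict | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full QC chain and return the filtered matrix plus its report.

    Stage order: call rate and minor-allele count (the read-time filters),
    indels, failed samples, HWE, LD pruning, per-sample missingness,
    relatedness.  Config defaults are the standard thresholds
    (0.80 call rate, MAC 10, HWE p<0.05 in >=6 populations, r^2>0.20,
    >25% missing, PI-HAT >0.20).
    """
    cfg = dict(DEFAULT_QC_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown QC config keys: {sorted(unknown)}")
        cfg.update(config)

    report = QcReport()
    g, st = filter_call_rate(g, cfg["min_call_rate"])
    report.add(st)
    g, st = filter_mac(g, cfg["min_mac"])
    report.add(st)
    g, st = drop_indels(g)
    report.add(st)
    g, st = drop_failed_samples(g, cfg["failed_sample_max_missing"])
    report.add(st)
    pm_live = pm.subset(g.sample_ids)
    min_pops = min(cfg["hwe_min_pops"], len(pm_live.populations))
    g, st = hwe_filter(g, pm_live, cfg["hwe_alpha"], min_pops)
    report.add(st)
    g, st = ld_prune(g, cfg["ld_r2_max"], cfg["ld_window"], cfg["ld_step"])
    report.add(st)
    g, st = drop_samples(g, cfg["max_missing"])
    report.add(st)
    rm = pihat(g)
    removed = resolve_related(rm, cfg["pihat_threshold"], individual_missingness(g))
    g2 = g.drop_samples(removed)
    report.add(_stage("relatedness", g, g2, pihat_threshold=cfg["pihat_threshold"]))
    report.validate()
    return g2, report
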