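"""End-to-end pipeline orchestration: qc -> stats -> simulate -> abc.

A run is configured by a single YAML file (unknown keys rejected), executes
into an output directory with one subdirectory per stage, and writes a
machine-readable manifest (versions, seeds, input hashes).  Stages whose
outputs already exist are skipped, so deleting one stage's directory and
rerunning recomputes only that stage and those after it.  With a fixed seed
the produced tables are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abc_rf import estimate_parameters, model_choice
from .io_core import read_popmap, read_vcf, write_popmap, write_vcf
from .popgen_stats import nj_bootstrap, pairwise_fst_table, pca, population_stats
from .scenario_engine import (
    ReferenceTable,
    ScenarioSpec,
    builtin_scenario,
    generate_reference_table,
    load_scenario,
    make_pseudo_observed,
    population_map_for,
    simulate_genotypes,
)
from .variant_qc import individual_missingness, pihat, run_qc

log = logging.getLogger("knotpop")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


_KNOWN_KEYS = {
    "vcf",
    "popmap",
    "outdir",
    "seed",
    "qc",
    "stats",
    "scenarios",
    "simulation",
    "abc",
    "demo",
}


@dataclass
class RunConfig:
    outdir: str
    vcf: str | None = None
    popmap: str | None = None
    seed: int = 0
    qc: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    scenarios: list[str] = field(default_factory=list)
    simulation: dict = field(default_factory=dict)
    abc: dict = field(default_factory=dict)
    demo: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in doc:
            raise ConfigError("config must set 'outdir'")
        return cls(**doc)


def _load_scenarios(names: list[str]) -> list[ScenarioSpec]:
    specs = []
    for name in names:
        if Path(name).exists():
            specs.append(load_scenario(name))
        else:
            specs.append(builtin_scenario(name))
    return specs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_demo_data(
    outdir: str,
    scenario: str = "step2_d",
    n_loci: int = 1000,
    missing: float = 0.045,
    seed: int = 0,
) -> tuple[str, str]:
    """Simulate a demonstration VCF + popmap under a bundled scenario's
    reference parameter values."""
    spec = builtin_scenario(scenario) if not Path(scenario).exists() else load_scenario(scenario)
    params = dict(spec.truth)
    if not params:
        rng = np.random.default_rng(seed)
        params = spec.priors.sample(rng)
    g = simulate_genotypes(spec.scenario, params, n_loci, missing, seed)
    pm = population_map_for(spec.scenario)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = write_vcf(g, str(out / "demo.vcf"))
    pop_path = write_popmap(pm, str(out / "demo.popmap.tsv"))
    return vcf_path, pop_path


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    Any stage error aborts with the stage name; completed stage outputs are
    preserved.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "knotpop_version": __version__,
        "seed": cfg.seed,
        "stages": {},
    }

    vcf_path, pop_path = cfg.vcf, cfg.popmap
    if cfg.demo:
        demo_dir = out / "demo"
        stage = "demo-data"
        t0 = time.time()
        if (demo_dir / "demo.vcf").exists():
            log.info("[%s] outputs exist, skipping", stage)
            vcf_path = str(demo_dir / "demo.vcf")
            pop_path = str(demo_dir / "demo.popmap.tsv")
        else:
            try:
                vcf_path, pop_path = make_demo_data(
                    str(demo_dir),
                    cfg.demo.get("scenario", "step2_d"),
                    int(cfg.demo.get("n_loci", 1000)),
                    float(cfg.demo.get("missing", 0.045)),
                    cfg.seed,
                )
            except Exception as exc:
                raise StageError(stage, exc) from exc
            manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    # ------------------------------------------------------------------- qc
    qc_dir = out / "qc"
    filtered_vcf = qc_dir / "filtered.vcf"
    if vcf_path is not None:
        stage = "qc"
        t0 = time.time()
        if filtered_vcf.exists():
            log.info("[%s] outputs exist, skipping", stage)
        else:
            try:
                qc_dir.mkdir(exist_ok=True)
                g = read_vcf(vcf_path)
                pm = read_popmap(pop_path, g)
                g2, report = run_qc(g, pm, cfg.qc or None)
                report.to_frame().to_csv(qc_dir / "qc_report.tsv", sep="\t", index=False)
                (qc_dir / "qc_report.json").write_text(report.to_json())
                rm = pihat(g2)
                rm.to_frame().to_csv(qc_dir / "relatedness.tsv", sep="\t")
                individual_missingness(g2).to_csv(qc_dir / "missingness.tsv", sep="\t")
                write_vcf(g2, str(filtered_vcf))
                pm.subset(g2.sample_ids)
                write_popmap(pm.subset(g2.sample_ids), str(qc_dir / "filtered.popmap.tsv"))
            except Exception as exc:
                raise StageError(stage, exc) from exc
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 2),
                "filtered_vcf_sha256": _sha256(filtered_vcf),
            }

        # -------------------------------------------------------------- stats
        stage = "stats"
        stats_dir = out / "stats"
        t0 = time.time()
        if cfg.stats.get("skip"):
            log.info("[%s] disabled for this run", stage)
        elif (stats_dir / "per_population.tsv").exists():
            log.info("[%s] outputs exist, skipping", stage)
        else:
            try:
                stats_dir.mkdir(exist_ok=True)
                g2 = read_vcf(str(filtered_vcf))
                pm2 = read_popmap(str(qc_dir / "filtered.popmap.tsv"), g2)
                rng = np.random.default_rng(cfg.seed)
                stats = population_stats(g2, pm2)
                pd.DataFrame(
                    [
                        {
                            "population": s.population,
                            "mean_pi": s.mean_pi,
                            "h_obs": s.h_obs,
                            "mean_fis": s.mean_fis,
                            "mean_tajimas_d": s.mean_tajimas_d,
                        }
                        for s in stats.values()
                    ]
                ).to_csv(stats_dir / "per_population.tsv", sep="\t", index=False)
                fst = pairwise_fst_table(
                    g2,
                    pm2,
                    n_boot=int(cfg.stats.get("n_boot", 500)),
                    n_perm=int(cfg.stats.get("n_perm", 1000)),
                    rng=rng,
                )
                fst.to_csv(stats_dir / "pairwise_fst.tsv", sep="\t", index=False)
                tree, support = nj_bootstrap(
                    g2, pm2, n_boot=int(cfg.stats.get("nj_boot", 1000)), rng=rng
                )
                (stats_dir / "nj_tree.nwk").write_text(str(tree))
                with open(stats_dir / "nj_support.tsv", "w") as fh:
                    fh.write("bipartition\tsupport_pct\n")
                    for split, pct in sorted(support.items(), key=lambda kv: -kv[1]):
                        fh.write(",".join(sorted(split)) + f"\t{pct:.1f}\n")
                pca(g2).scores.to_csv(stats_dir / "pca_scores.tsv", sep="\t")
            except Exception as exc:
                raise StageError(stage, exc) from exc
            manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    # --------------------------------------------------------------- simulate
    ref_path = out / "simulate" / "reference_table.tsv"
    if cfg.scenarios:
        stage = "simulate"
        t0 = time.time()
        if ref_path.exists():
            log.info("[%s] outputs exist, skipping", stage)
        else:
            try:
                ref_path.parent.mkdir(exist_ok=True)
                specs = _load_scenarios(cfg.scenarios)
                rt = generate_reference_table(
                    specs,
                    n_per_scenario=int(cfg.simulation.get("n_per_scenario", 1000)),
                    n_loci=int(cfg.simulation.get("n_loci", 1000)),
                    missing=cfg.simulation.get("missing", 0.045),
                    seed=cfg.seed,
                )
                rt.to_tsv(str(ref_path))
            except Exception as exc:
                raise StageError(stage, exc) from exc
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 2),
                "reference_table_sha256": _sha256(ref_path),
            }

        # ---------------------------------------------------------------- abc
        stage = "abc"
        abc_dir = out / "abc"
        t0 = time.time()
        if (abc_dir / "model_choice.json").exists():
            log.info("[%s] outputs exist, skipping", stage)
        else:
            try:
                abc_dir.mkdir(exist_ok=True)
                rt = ReferenceTable.from_tsv(str(ref_path))
                specs = _load_scenarios(cfg.scenarios)
                observed = cfg.abc.get("observed")
                if observed is not None:
                    obs = pd.read_csv(observed, sep="\t").iloc[0]
                else:
                    # pseudo-observed dataset from the first scenario's
                    # reference values (demonstration mode)
                    spec0 = specs[0]
                    params = dict(spec0.truth) or spec0.priors.sample(
                        np.random.default_rng(cfg.seed + 1)
                    )
                    seen: dict = {}
                    for sp in specs:
                        for trio in sp.scenario.admixture_trios():
                            seen.setdefault(trio)
                    obs = make_pseudo_observed(
                        spec0,
                        params,
                        int(cfg.simulation.get("n_loci", 1000)),
                        cfg.simulation.get("missing", 0.045),
                        seed=cfg.seed + 1,
                        trios=list(seen),
                    )
                n_trees = int(cfg.abc.get("n_trees", 1000))
                result = None
                if len(rt.scenario_labels) >= 2:
                    result = model_choice(rt, obs, n_trees=n_trees, seed=cfg.seed)
                    (abc_dir / "model_choice.json").write_text(
                        json.dumps(
                            {
                                "selected": result.selected,
                                "votes": result.votes.to_dict(),
                                "posterior_prob": result.posterior_prob,
                                "prior_error_rate": result.prior_error_rate,
                                "n_trees": result.n_trees,
                            },
                            indent=2,
                        )
                    )
                    (abc_dir / "model_choice.txt").write_text(result.summary())
                best = cfg.abc.get("best_scenario") or (
                    result.selected if result else rt.scenario_labels[0]
                )
                post = estimate_parameters(
                    rt.for_scenario(best),
                    obs,
                    n_trees=int(cfg.abc.get("n_trees_regression", n_trees)),
                    seed=cfg.seed,
                )
                post.estimates.to_csv(abc_dir / "parameter_posterior.tsv", sep="\t")
                post.converted().to_csv(abc_dir / "parameter_posterior_years.tsv", sep="\t")
                (abc_dir / "parameter_posterior.txt").write_text(post.summary())
            except Exception as exc:
                raise StageError(stage, exc) from exc
            manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
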