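"""Declarative demographic scenarios and the coalescent SNP simulator.

A :class:`Scenario` is an ordered backward-time event list (population
merges, pulse admixtures, size changes) over a set of sampled populations,
with numeric fields optionally bound to named parameters drawn from a
:class:`PriorSpec`.  The simulator emits unlinked biallelic 150-bp RAD-style
SNP loci: one segregating site per locus, placed uniformly on the coalescent
tree (fixed-S conditioning, reproducing the ascertainment of discovered
SNPs), with per-population missingness masked at template rates.  No
per-generation mutation rate enters the simulation; substitution rates are
used only for reporting conversions downstream.

Scenario files are YAML; see ``knotpop/scenarios/`` for the bundled
divergence/admixture scenario library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import _coalescent
from .io_core import MISSING, GenotypeMatrix, PopulationMap, VARIANT_META_COLUMNS


class ScenarioError(ValueError):
    """Inconsistent scenario definition (events, sizes, or priors)."""


# ------------------------------------------------------------------- scenarios

Value = float | str  # numeric literal or parameter name


@dataclass
class Population:
    label: str
    samples: int  # diploid sample size
    size: Value  # diploid effective size (or parameter name)


@dataclass
class Event:
    kind: str  # 'merge' | 'admix' | 'size'
    time: Value
    source: str | None = None  # merge: emptied population
    dest: str | None = None  # merge: receiving population
    target: str | None = None  # admix: population receiving the pulse (forward)
    source1: str | None = None  # admix: ancestor with probability `rate`
    source2: str | None = None  # admix: ancestor with probability 1 - `rate`
    rate: Value | None = None
    pop: str | None = None  # size: population whose size changes
    size: Value | None = None


@dataclass
class Scenario:
    name: str
    populations: list[Population]
    events: list[Event]

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def admixture_trios(self) -> list[tuple[str, str, str]]:
        """(target | source1, source2) trios from admixture events with two
        distinct external sources (pulses into an existing population are
        excluded, since source2 == target there)."""
        trios = []
        for ev in self.events:
            if ev.kind == "admix" and ev.target not in (ev.source1, ev.source2):
                trios.append((ev.target, ev.source1, ev.source2))
        return trios

    def parameter_names(self) -> list[str]:
        names: dict[str, None] = {}
        for p in self.populations:
            if isinstance(p.size, str):
                names.setdefault(p.size)
        for ev in self.events:
            for v in (ev.time, ev.rate, ev.size):
                if isinstance(v, str):
                    names.setdefault(v)
        return list(names)

    # ------------------------------------------------------------ binding
    def bind(self, params: dict[str, float]) -> "BoundScenario":
        """Resolve parameters to numbers, order events, and validate."""

        def val(v: Value | None, what: str) -> float:
            if v is None:
                raise ScenarioError(f"{self.name}: missing {what}")
            if isinstance(v, str):
                if v not in params:
                    raise ScenarioError(f"{self.name}: parameter {v!r} not supplied")
                return float(params[v])
            return float(v)

        idx = {p.label: i for i, p in enumerate(self.populations)}
        sizes = np.array([val(p.size, f"size of {p.label}") for p in self.populations])
        if (sizes <= 0).any():
            raise ScenarioError(f"{self.name}: population sizes must be positive")

        rows = []
        for ev in self.events:
            t = val(ev.time, f"time of {ev.kind} event")
            if t <= 0:
                raise ScenarioError(f"{self.name}: event times must be positive")
            if ev.kind == "merge":
                rows.append((t, _coalescent.EV_MERGE, idx[ev.source], idx[ev.dest], -1, 0.0))
            elif ev.kind == "admix":
                r = val(ev.rate, "admixture rate")
                if not 0.0 <= r <= 1.0:
                    raise ScenarioError(f"{self.name}: admixture rate outside [0,1]")
                rows.append(
                    (t, _coalescent.EV_ADMIX, idx[ev.target], idx[ev.source1], idx[ev.source2], r)
                )
            elif ev.kind == "size":
                rows.append(
                    (t, _coalescent.EV_SIZE, idx[ev.pop], -1, -1, val(ev.size, "new size"))
                )
            else:
                raise ScenarioError(f"{self.name}: unknown event kind {ev.kind!r}")
        rows.sort(key=lambda r: (r[0], r[1]))

        bound = BoundScenario(
            name=self.name,
            labels=self.labels,
            samples=np.array([p.samples for p in self.populations], dtype=np.int64),
            sizes=sizes,
            ev_time=np.array([r[0] for r in rows]),
            ev_kind=np.array([r[1] for r in rows], dtype=np.int64),
            ev_a=np.array([r[2] for r in rows], dtype=np.int64),
            ev_b=np.array([r[3] for r in rows], dtype=np.int64),
            ev_c=np.array([r[4] for r in rows], dtype=np.int64),
            ev_x=np.array([r[5] for r in rows]),
        )
        bound.validate()
        return bound


@dataclass
class BoundScenario:
    """A scenario with all parameters resolved, ready for the kernel."""

    name: str
    labels: list[str]
    samples: np.ndarray
    sizes: np.ndarray
    ev_time: np.ndarray
    ev_kind: np.ndarray
    ev_a: np.ndarray
    ev_b: np.ndarray
    ev_c: np.ndarray
    ev_x: np.ndarray

    def validate(self) -> None:
        """Check that referenced populations are alive when each event fires
        and that all sampled populations coalesce into a single root branch."""
        alive = set(range(len(self.labels)))
        for i in range(len(self.ev_time)):
            kind = self.ev_kind[i]
            a, b, c = self.ev_a[i], self.ev_b[i], self.ev_c[i]
            if kind == _coalescent.EV_MERGE:
                if a not in alive or b not in alive:
                    raise ScenarioError(
                        f"{self.name}: merge at t={self.ev_time[i]} references a merged-away population"
                    )
                alive.discard(int(a))
            elif kind == _coalescent.EV_ADMIX:
                if a not in alive or b not in alive or c not in alive:
                    raise ScenarioError(
                        f"{self.name}: admixture at t={self.ev_time[i]} references a merged-away population"
                    )
                if a != b and a != c:
                    # founding pulse: every lineage leaves the target, which
                    # does not exist further back in time
                    alive.discard(int(a))
            else:
                if a not in alive:
                    raise ScenarioError(
                        f"{self.name}: size change at t={self.ev_time[i]} on merged-away population"
                    )
        if len(alive) != 1:
            raise ScenarioError(
                f"{self.name}: populations never coalesce to a single root "
                f"({len(alive)} branches remain)"
            )


# ---------------------------------------------------------------------- priors


@dataclass
class Prior:
    name: str
    dist: str  # 'uniform' | 'loguniform'
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ScenarioError(f"unknown prior distribution {self.dist!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low <= self.high):
            raise ScenarioError(f"prior {self.name}: bounds must be finite with low <= high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ScenarioError(f"prior {self.name}: loguniform needs positive bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass
class PriorSpec:
    """Per-parameter marginals plus pairwise order constraints (a < b)."""

    priors: dict[str, Prior]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.priors) | set(self.fixed)
        for a, b in self.constraints:
            if a not in known or b not in known:
                raise ScenarioError(f"constraint {a} < {b} references unknown parameter")

    def sample(self, rng: np.random.Generator, max_rejections: int = 1_000_000) -> dict[str, float]:
        """Draw one constraint-satisfying parameter set (rejection sampling)."""
        attempts = 0
        while True:
            params = {name: prior.draw(rng) for name, prior in self.priors.items()}
            params.update(self.fixed)
            if all(params[a] < params[b] for a, b in self.constraints):
                return params
            attempts += 1
            if attempts >= max_rejections:
                raise ScenarioError("prior constraints look infeasible (rejection cap reached)")


def sample_prior(ps: PriorSpec, rng: np.random.Generator) -> dict[str, float]:
    return ps.sample(rng)


# ---------------------------------------------------------------- YAML loading


@dataclass
class ScenarioSpec:
    """A scenario bundled with its priors and reference parameter values."""

    scenario: Scenario
    priors: PriorSpec
    truth: dict[str, float] = field(default_factory=dict)
    description: str = ""


def _parse_scenario_dict(doc: dict) -> ScenarioSpec:
    pops = [
        Population(d["label"], int(d["samples"]), d["size"]) for d in doc["populations"]
    ]
    events = []
    for d in doc.get("events", []):
        d = dict(d)
        kind = d.pop("kind")
        new_dest_size = d.pop("new_dest_size", None)
        ev = Event(kind=kind, **d)
        events.append(ev)
        if new_dest_size is not None:
            if kind != "merge":
                raise ScenarioError("new_dest_size is only valid on merge events")
            events.append(Event(kind="size", time=ev.time, pop=ev.dest, size=new_dest_size))
    scenario = Scenario(doc["name"], pops, events)
    priors = PriorSpec(
        priors={
            name: Prior(name, d.get("dist", "uniform"), float(d["low"]), float(d["high"]))
            for name, d in doc.get("priors", {}).items()
        },
        constraints=[(a, b) for a, op, b in doc.get("constraints", []) if op == "<"]
        + [(b, a) for a, op, b in doc.get("constraints", []) if op == ">"],
        fixed={k: float(v) for k, v in doc.get("fixed", {}).items()},
    )
    declared = set(priors.priors) | set(priors.fixed)
    missing = set(scenario.parameter_names()) - declared
    if missing:
        raise ScenarioError(f"{scenario.name}: undeclared parameters {sorted(missing)}")
    truth = {k: float(v) for k, v in doc.get("truth", {}).items()}
    return ScenarioSpec(scenario, priors, truth, doc.get("description", ""))


def load_scenario(path: str) -> ScenarioSpec:
    with open(path, encoding="utf-8") as fh:
        return _parse_scenario_dict(yaml.safe_load(fh))


def builtin_scenario_names() -> list[str]:
    pkg = resources.files("knotpop.scenarios")
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def builtin_scenario(name: str) -> ScenarioSpec:
    pkg = resources.files("knotpop.scenarios")
    text = (pkg / f"{name}.yaml").read_text(encoding="utf-8")
    return _parse_scenario_dict(yaml.safe_load(text))


# ------------------------------------------------------------------ simulation


def _seed_words(seed: int, start: int, count: int) -> np.ndarray:
    """Counter-based per-locus seed stream: deterministic, order-independent."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(start + count, dtype=np.uint32)[start:]


def _resolve_missing(bound: BoundScenario, missing) -> np.ndarray:
    if missing is None:
        rates = np.zeros(len(bound.labels))
    elif np.isscalar(missing):
        rates = np.full(len(bound.labels), float(missing))
    else:
        rates = np.array([float(missing.get(lbl, 0.0)) for lbl in bound.labels])
    if ((rates < 0) | (rates >= 1)).any():
        raise ScenarioError("missingness rates must be in [0, 1)")
    return rates


def _raw_loci(bound: BoundScenario, n_loci: int, seed: int, seed_offset: int = 0):
    n_tips = int(2 * bound.samples.sum())
    derived = np.empty((n_loci, n_tips), dtype=np.uint8)
    tmrca = np.empty(n_loci)
    seeds = _seed_words(seed, seed_offset, n_loci)
    _coalescent.simulate_loci(
        seeds,
        2 * bound.samples,
        bound.sizes,
        bound.ev_time,
        bound.ev_kind,
        bound.ev_a,
        bound.ev_b,
        bound.ev_c,
        bound.ev_x,
        derived,
        tmrca,
    )
    return derived, tmrca


def simulate_tmrca(
    scenario: Scenario, params: dict[str, float], n_loci: int, seed: int
) -> np.ndarray:
    """Per-locus time to the most recent common ancestor (generations)."""
    bound = scenario.bind(params)
    _, tmrca = _raw_loci(bound, n_loci, seed)
    return tmrca


def simulate_genotypes(
    scenario: Scenario,
    params: dict[str, float],
    n_loci: int,
    missing: float | dict[str, float] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate unlinked biallelic SNP loci under a demographic scenario.

    Returns a GenotypeMatrix with one SNP per 150-bp locus; the derived
    (mutant) allele is coded as ALT.  Per-population missingness is applied
    as independent per-call masking at the template rates; loci monomorphic
    after masking are redrawn so the emitted locus count stays fixed.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    bound = scenario.bind(params)
    rates = _resolve_missing(bound, missing)
    derived, _ = _raw_loci(bound, n_loci, seed)

    n_ind = int(bound.samples.sum())
    dos = (derived[:, 0::2] + derived[:, 1::2]).astype(np.int8).T  # samples x loci
    sample_ids = []
    pop_of_ind = []
    for lbl, k in zip(bound.labels, bound.samples):
        for i in range(int(k)):
            sample_ids.append(f"{lbl}_{i:02d}")
            pop_of_ind.append(lbl)
    rate_of_ind = np.array([rates[bound.labels.index(p)] for p in pop_of_ind])

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if rates.any():
        mask = rng.random((n_ind, n_loci)) < rate_of_ind[:, None]
        dos[mask] = MISSING
        # redraw loci that lost their polymorphism to masking
        offset = n_loci
        for _ in range(100):
            called = dos != MISSING
            any_called = called.any(axis=0)
            mx = np.where(called, dos, -9).max(axis=0)
            mn = np.where(called, dos, 9).min(axis=0)
            # monomorphic: every called allele is REF (max dosage 0) or ALT (min 2)
            bad = np.flatnonzero(~any_called | (mx == 0) | (mn == 2))
            if len(bad) == 0:
                break
            redo, _ = _raw_loci(bound, len(bad), seed, seed_offset=offset)
            offset += len(bad)
            new = (redo[:, 0::2] + redo[:, 1::2]).astype(np.int8).T
            remask = rng.random((n_ind, len(bad))) < rate_of_ind[:, None]
            new[remask] = MISSING
            dos[:, bad] = new
        else:
            raise ScenarioError("could not produce polymorphic loci under this missingness")

    meta = pd.DataFrame(
        {
            "contig": [f"locus_{j:06d}" for j in range(n_loci)],
            "pos": np.full(n_loci, 75),
            "ref": "A",
            "alt": "T",
            "locus_id": [f"locus_{j:06d}" for j in range(n_loci)],
            "is_indel": False,
        }
    )[VARIANT_META_COLUMNS]
    return GenotypeMatrix(sample_ids, meta, dos)


def population_map_for(scenario: Scenario) -> PopulationMap:
    assignments = {}
    for pop in scenario.populations:
        for i in range(pop.samples):
            assignments[f"{pop.label}_{i:02d}"] = pop.label
    return PopulationMap(assignments, [p.label for p in scenario.populations])


# -------------------------------------------------------------- reference table


@dataclass
class ReferenceTable:
    """ABC training set: one row per simulation (label, parameters, summaries)."""

    table: pd.DataFrame
    summary_cols: list[str]
    param_cols: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def scenario_labels(self) -> list[str]:
        return list(pd.unique(self.table["scenario"]))

    def for_scenario(self, name: str) -> "ReferenceTable":
        sub = self.table[self.table["scenario"] == name].reset_index(drop=True)
        params = [c for c in self.param_cols if sub[c].notna().all()]
        return ReferenceTable(sub, list(self.summary_cols), params, dict(self.provenance))

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False)
        return str(path)

    @classmethod
    def from_tsv(cls, path: str, summary_prefix: str = "ss_") -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        summary_cols = [c for c in df.columns if c.startswith(summary_prefix)]
        param_cols = [c for c in df.columns if c not in summary_cols and c != "scenario"]
        return cls(df, summary_cols, param_cols)


def generate_reference_table(
    specs: list[ScenarioSpec],
    n_per_scenario: int,
    n_loci: int,
    missing: float | dict[str, float] | None = None,
    seed: int = 0,
    trios: list[tuple[str, str, str]] | None = None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate the ABC training set across scenarios.

    Every scenario must share the sampled-population set so that summary
    vectors are schema-compatible.  Deterministic under a fixed seed.
    """
    from .abc_summaries import summarize, summary_names

    labels0 = specs[0].scenario.labels
    samples0 = [p.samples for p in specs[0].scenario.populations]
    for spec in specs[1:]:
        if spec.scenario.labels != labels0 or [
            p.samples for p in spec.scenario.populations
        ] != samples0:
            raise ScenarioError("scenarios disagree on sampled populations")
    if trios is None:
        seen: dict[tuple[str, str, str], None] = {}
        for spec in specs:
            for trio in spec.scenario.admixture_trios():
                seen.setdefault(trio)
        trios = list(seen)

    pm = population_map_for(specs[0].scenario)
    param_cols: dict[str, None] = {}
    for spec in specs:
        for name in spec.scenario.parameter_names():
            param_cols.setdefault(name)
    param_cols = list(param_cols)
    summary_cols = [f"ss_{n}" for n in summary_names(pm.populations, trios)]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * n_per_scenario)
    rows = []
    it = 0
    for spec in specs:
        for _ in range(n_per_scenario):
            child = children[it]
            it += 1
            rng = np.random.default_rng(child)
            params = spec.priors.sample(rng)
            sim_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31 - 1)
            g = simulate_genotypes(spec.scenario, params, n_loci, missing, sim_seed)
            summ = summarize(g, pm, trios)
            row = {"scenario": spec.scenario.name}
            row.update({c: params.get(c, np.nan) for c in param_cols})
            row.update({f"ss_{k}": v for k, v in summ.items()})
            rows.append(row)
            if progress and it % 100 == 0:
                print(f"  simulated {it}/{len(children)} datasets", flush=True)
    table = pd.DataFrame(rows, columns=["scenario"] + param_cols + summary_cols)
    if table[summary_cols].isna().any().any():
        raise ScenarioError("summary vector contains NaN")
    return ReferenceTable(
        table,
        summary_cols,
        param_cols,
        provenance={"seed": seed, "n_loci": n_loci, "n_per_scenario": n_per_scenario},
    )


def make_pseudo_observed(
    spec: ScenarioSpec,
    params: dict[str, float],
    n_loci: int,
    missing: float | dict[str, float] | None = None,
    seed: int = 0,
    trios: list[tuple[str, str, str]] | None = None,
) -> pd.Series:
    """One simulation at fixed parameters, summarised identically to training rows."""
    from .abc_summaries import summarize

    if trios is None:
        trios = spec.scenario.admixture_trios()
    pm = population_map_for(spec.scenario)
    g = simulate_genotypes(spec.scenario, params, n_loci, missing, seed)
    summ = summarize(g, pm, trios)
    return pd.Series({f"ss_{k}": v for k, v in summ.items()})
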