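"""Core genotype data model and standard-format I/O.

The central container is :class:`GenotypeMatrix`: a samples x variants table of
diploid ALT-allele dosages in {0, 1, 2} with ``MISSING = -1`` for no-calls,
plus per-variant metadata (contig, 1-based position, ref/alt alleles, RAD
locus id, indel flag).  Dosages count ALT alleles exactly as written in the
VCF; minor-allele frequencies are computed downstream, never by re-polarising
storage.  Variants are grouped into RAD loci — by default one locus per contig,
matching a de novo RAD reference in which each contig is one 150-bp fragment.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_META_COLUMNS = ["contig", "pos", "ref", "alt", "locus_id", "is_indel"]


class VcfFormatError(ValueError):
    """Malformed VCF input (bad header, multiallelic record, non-diploid GT)."""


class PopmapError(ValueError):
    """Sample/population mapping does not cover the genotype matrix."""


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows of ``calls``).
    variant_meta : pandas.DataFrame
        One row per variant with columns ``contig, pos, ref, alt, locus_id,
        is_indel``; variants within a locus are position-sorted.
    calls : ndarray of int8, shape (n_samples, n_variants)
        ALT-allele dosage in {0, 1, 2} or ``MISSING`` (-1).
    """

    sample_ids: list[str]
    variant_meta: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x variants)")
        if self.calls.shape != (len(self.sample_ids), len(self.variant_meta)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.variant_meta)} variants)"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,MISSING}")
        missing_cols = set(VARIANT_META_COLUMNS) - set(self.variant_meta.columns)
        if missing_cols:
            raise ValueError(f"variant_meta missing columns: {sorted(missing_cols)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.variant_meta = self.variant_meta.reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_meta)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called (non-missing) cells."""
        return self.calls != MISSING

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset by variant index (bool mask or integer positions)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_meta=self.variant_meta.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variant_meta=self.variant_meta.copy(),
            calls=self.calls[index, :],
        )

    def drop_samples(self, ids: set[str]) -> "GenotypeMatrix":
        keep = [i for i, s in enumerate(self.sample_ids) if s not in ids]
        return self.take_samples(np.asarray(keep, dtype=int))

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.calls, other.calls)
            and self.variant_meta[VARIANT_META_COLUMNS].equals(
                other.variant_meta[VARIANT_META_COLUMNS]
            )
        )


@dataclass
class PopulationMap:
    """Assignment of each sample to exactly one population.

    ``populations`` preserves first-appearance order from the popmap file,
    which fixes the ordering of all downstream per-population outputs.
    """

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: dict[str, None] = {}
            for pop in self.assignments.values():
                seen.setdefault(pop)
            self.populations = list(seen)

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def indices_for(self, pop: str, g: GenotypeMatrix) -> np.ndarray:
        """Row indices of ``g`` belonging to ``pop`` (in matrix order)."""
        return np.asarray(
            [i for i, s in enumerate(g.sample_ids) if self.assignments.get(s) == pop],
            dtype=int,
        )

    def subset(self, sample_ids: list[str]) -> "PopulationMap":
        keep = {s: self.assignments[s] for s in sample_ids}
        return PopulationMap(keep, [p for p in self.populations if p in set(keep.values())])


# --------------------------------------------------------------------------- VCF
def read_vcf(path: str, keep_indels: bool = True, locus_info_tag: str | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF (4.x, plain or gzip) into a GenotypeMatrix.

    Dosage is the ALT-allele count of the diploid GT; ``./.`` becomes MISSING.
    Multiallelic records are rejected.  ``locus_id`` defaults to the contig
    name (one RAD fragment per contig) unless ``locus_info_tag`` names an INFO
    field to use instead.  Indels (ref/alt length mismatch) are flagged, and
    dropped here when ``keep_indels`` is False.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises on malformed headers
        raise VcfFormatError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    meta_rows = []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise VcfFormatError(
                f"multiallelic record at {var.CHROM}:{var.POS}; split or filter upstream"
            )
        alt = var.ALT[0]
        is_indel = len(var.REF) != len(alt) or len(var.REF) != 1
        if is_indel and not keep_indels:
            continue
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise VcfFormatError(
                    f"non-diploid GT for sample {samples[i]} at {var.CHROM}:{var.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                continue
            dos[i] = alleles[0] + alleles[1]
        locus = var.CHROM
        if locus_info_tag is not None:
            tag = var.INFO.get(locus_info_tag)
            if tag is not None:
                locus = str(tag)
        meta_rows.append((var.CHROM, var.POS, var.REF, alt, locus, bool(is_indel)))
        columns.append(dos)

    meta = pd.DataFrame(meta_rows, columns=VARIANT_META_COLUMNS)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    g = GenotypeMatrix(samples, meta, calls)
    return _sort_variants(g)


def _sort_variants(g: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((g.variant_meta["pos"].to_numpy(), g.variant_meta["contig"].to_numpy()))
    if np.array_equal(order, np.arange(g.n_variants)):
        return g
    return g.take_variants(order)


def write_vcf(g: GenotypeMatrix, path: str) -> str:
    """Write a GenotypeMatrix as VCF 4.2 with GT-only FORMAT.

    Records are emitted in deterministic (contig, position) order; MISSING
    cells become ``./.``.  A ``.gz`` suffix selects gzip compression.
    """
    g = _sort_variants(g)
    opener = gzip.open if str(path).endswith(".gz") else open
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(g.variant_meta["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        meta = g.variant_meta
        for j in range(g.n_variants):
            row = meta.iloc[j]
            gts = "\t".join(gt_str[int(d)] for d in g.calls[:, j])
            fh.write(
                f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return str(path)


def read_popmap(path: str, g: GenotypeMatrix | None = None) -> PopulationMap:
    """Read a two-column TSV (sample <tab> population) into a PopulationMap.

    When ``g`` is given, coverage is checked both ways: every matrix sample
    must be mapped, and no popmap row may reference an unknown sample.
    """
    assignments: dict[str, str] = {}
    populations: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PopmapError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, pop = parts
            if sample in assignments:
                raise PopmapError(f"{path}:{lineno}: duplicated sample {sample!r}")
            assignments[sample] = pop
            populations.setdefault(pop)
    pm = PopulationMap(assignments, list(populations))
    if g is not None:
        matrix_samples = set(g.sample_ids)
        unmapped = matrix_samples - set(assignments)
        if unmapped:
            raise PopmapError(f"samples missing from popmap: {sorted(unmapped)}")
        unknown = set(assignments) - matrix_samples
        if unknown:
            raise PopmapError(f"popmap rows for unknown samples: {sorted(unknown)}")
    return pm


def write_popmap(pm: PopulationMap, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, pop in pm.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
    return str(path)
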