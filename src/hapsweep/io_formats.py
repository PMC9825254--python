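"""Phased haplotype IO and the DGRP-style preprocessing filters.

The universal unit of analysis is the :class:`HaplotypeMatrix`: ``n`` phased
haplotypes over ``m`` biallelic sites on one chromosome arm.  Residual
heterozygosity in inbred-line panels is represented purely as MISSING — no
heterozygous genotype state exists internally.  Coordinates are 1-based
inclusive for sites and half-open ``[start, end)`` for recombination-map
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a missing allele call.
MISSING = -1

AUTOSOME = "autosome"
X = "X"


class HaplotypeDataError(ValueError):
    """Raised for malformed or empty haplotype inputs."""


@dataclass
class HaplotypeMatrix:
    """``n`` phased haplotypes x ``m`` biallelic sites.

    Parameters
    ----------
    haplotypes:
        ``(n, m)`` int8 array with entries in ``{0, 1, MISSING}``.
    positions:
        Strictly increasing 1-based bp coordinates, length ``m``.
    chrom_label:
        Chromosome arm name (e.g. ``"2L"`` or ``"X"``).
    chrom_class:
        ``"autosome"`` or ``"X"``.
    sample_ids:
        One identifier per haplotype row.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom_label: str = "chr"
    chrom_class: str = AUTOSOME
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise HaplotypeDataError("haplotypes must be a 2-D matrix")
        n, m = self.haplotypes.shape
        if self.positions.shape != (m,):
            raise HaplotypeDataError("positions length must match column count")
        if m and (np.any(np.diff(self.positions) <= 0) or self.positions[0] < 1):
            raise HaplotypeDataError("positions must be strictly increasing and >= 1")
        if self.chrom_class not in (AUTOSOME, X):
            raise HaplotypeDataError(f"unknown chrom_class {self.chrom_class!r}")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise HaplotypeDataError("sample_ids length must match row count")
        if m and np.any((self.haplotypes == MISSING).all(axis=0)):
            raise HaplotypeDataError("every column must have at least one call")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-haplotype fraction of MISSING calls."""
        if self.m == 0:
            return np.zeros(self.n)
        return (self.haplotypes == MISSING).mean(axis=1)

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        return replace(
            self,
            haplotypes=self.haplotypes[:, index],
            positions=self.positions[index],
            sample_ids=list(self.sample_ids),
        )

    def take_haplotypes(self, index: np.ndarray) -> "HaplotypeMatrix":
        return replace(
            self,
            haplotypes=self.haplotypes[index, :],
            positions=self.positions.copy(),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(index)],
        )


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination map, rates in cM/bp.

    ``intervals`` is a DataFrame with columns ``chrom``, ``start``, ``end``
    (half-open, bp) and ``rate`` (cM/bp).
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "rate"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (df["rate"] < 0).any():
            raise ValueError("recombination rates must be >= 0")
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must satisfy start < end")
        for _, grp in df.groupby("chrom"):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError("intervals overlap within a chromosome")
        self.intervals = df

    def rate_at(self, chrom: str, pos: int) -> float:
        """Rate of the interval containing 1-based ``pos`` (NaN outside the map)."""
        df = self.intervals
        hit = df[(df["chrom"] == chrom) & (df["start"] <= pos) & (pos < df["end"])]
        return float(hit["rate"].iloc[0]) if len(hit) else float("nan")

    def low_recombination_overlap(
        self, chrom: str, start: int, end: int, min_rate: float
    ) -> bool:
        """True if ``[start, end]`` overlaps any interval with rate < ``min_rate``."""
        df = self.intervals
        sel = df[(df["chrom"] == chrom) & (df["start"] <= end) & (df["end"] > start)]
        return bool((sel["rate"] < min_rate).any())

    def total_genetic_length_cm(self) -> float:
        df = self.intervals
        return float(((df["end"] - df["start"]) * df["rate"]).sum())


@dataclass
class IBDTable:
    """Symmetric pairwise genome-wide IBD fractions; the diagonal is ignored."""

    ids: list[str]
    values: np.ndarray  # (n, n) in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("IBD matrix shape must match number of ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("IBD matrix must be symmetric")

    @classmethod
    def from_pairs(cls, pairs, ids=None) -> "IBDTable":
        """Build from an iterable of ``(id_a, id_b, fraction)`` records.

        Unlisted pairs default to 0.  ``ids`` may enumerate samples with no
        recorded pair at all.
        """
        pairs = list(pairs)
        all_ids = list(ids) if ids is not None else []
        seen = set(all_ids)
        for a, b, _ in pairs:
            for x in (a, b):
                if x not in seen:
                    seen.add(x)
                    all_ids.append(x)
        index = {s: i for i, s in enumerate(all_ids)}
        vals = np.zeros((len(all_ids), len(all_ids)))
        for a, b, f in pairs:
            vals[index[a], index[b]] = f
            vals[index[b], index[a]] = f
        return cls(all_ids, vals)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_phased_vcf(path, chrom_class: str = AUTOSOME, force_phase: bool = False) -> HaplotypeMatrix:
    """Read phased diploid genotypes from a VCF into a HaplotypeMatrix.

    Two haplotypes are emitted per diploid sample, in sample order then allele
    index.  Non-biallelic SNP records are skipped (count logged); missing or
    half-called alleles become :data:`MISSING`.  Unphased het genotypes raise
    unless ``force_phase`` is set.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    chrom = None
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased and not force_phase and a0 != a1 and a0 >= 0 and a1 >= 0:
                raise HaplotypeDataError(
                    f"unphased genotype at {var.CHROM}:{var.POS} sample "
                    f"{samples[i]}; pass force_phase=True to accept as-is"
                )
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        rows.append(col)
        positions.append(var.POS)
        chrom = var.CHROM
    if n_skipped:
        log.info("read_phased_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise HaplotypeDataError("no biallelic SNPs found in VCF")
    hap = np.stack(rows, axis=1)
    sample_ids = [f"{s}|{k}" for s in samples for k in (1, 2)]
    return HaplotypeMatrix(hap, np.asarray(positions), chrom or "chr", chrom_class, sample_ids)


def write_phased_vcf(mat: HaplotypeMatrix, path) -> None:
    """Write a HaplotypeMatrix as a minimal phased VCF (pairs of rows = one sample)."""
    if mat.n % 2:
        raise HaplotypeDataError("VCF output needs an even number of haplotypes")
    samples = []
    for i in range(0, mat.n, 2):
        base = mat.sample_ids[i]
        samples.append(base[:-2] if base.endswith("|1") else base)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={mat.chrom_label}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(mat.m):
            gts = []
            for i in range(0, mat.n, 2):
                a = mat.haplotypes[i, j]
                b = mat.haplotypes[i + 1, j]
                gts.append(f"{'.' if a == MISSING else a}|{'.' if b == MISSING else b}")
            fh.write(
                f"{mat.chrom_label}\t{mat.positions[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Auxiliary whitespace "sites" table (fixture format)
# ---------------------------------------------------------------------------

def read_sites_table(path, chrom_class: str = AUTOSOME, chrom_label: str = "chr") -> HaplotypeMatrix:
    """Read the whitespace format: one line per site, ``position  alleles``.

    ``alleles`` is a string over ``{0, 1, ., N}`` with one character per
    haplotype ('.' or 'N' = missing).
    """
    positions, cols = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, alleles = line.split()
            positions.append(int(pos))
            cols.append([MISSING if c in ".N" else int(c) for c in alleles])
    if not cols:
        raise HaplotypeDataError("empty sites table")
    hap = np.asarray(cols, dtype=np.int8).T
    return HaplotypeMatrix(hap, np.asarray(positions), chrom_label, chrom_class)


def write_sites_table(mat: HaplotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for j in range(mat.m):
            alleles = "".join(
                "." if a == MISSING else str(int(a)) for a in mat.haplotypes[:, j]
            )
            fh.write(f"{mat.positions[j]}\t{alleles}\n")


def read_recombination_map(path) -> RecombinationMap:
    """Read a 4-column tab-separated map: chrom, start, end (half-open), cM/bp."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "rate"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "rate": float},
    )
    return RecombinationMap(df)


def write_recombination_map(rmap: RecombinationMap, path) -> None:
    rmap.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

def ibd_filter(ibd: IBDTable, threshold: float = 0.20) -> list[str]:
    """Drop every sample whose max pairwise IBD with any other exceeds ``threshold``.

    Removal is simultaneous — computed once on the original table, not
    re-evaluated after each removal.  Returns the retained ids in input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not ibd.ids:
        raise ValueError("empty IBD table")
    vals = ibd.values.copy()
    np.fill_diagonal(vals, 0.0)
    worst = vals.max(axis=1) if len(ibd.ids) > 1 else np.zeros(1)
    return [s for s, w in zip(ibd.ids, worst) if w <= threshold]


def site_call_filter(mat: HaplotypeMatrix, min_call_fraction: float = 0.5) -> HaplotypeMatrix:
    """Drop columns called in fewer than ``min_call_fraction`` of haplotypes."""
    if not 0 < min_call_fraction <= 1:
        raise ValueError("min_call_fraction must be in (0, 1]")
    called = (mat.haplotypes != MISSING).mean(axis=0)
    keep = np.flatnonzero(called >= min_call_fraction)
    if keep.size == 0:
        raise HaplotypeDataError("site_call_filter removed every column")
    if keep.size < mat.m:
        log.info("site_call_filter: dropped %d of %d sites", mat.m - keep.size, mat.m)
    return mat.take_sites(keep)


def top_complete_subsample(mat: HaplotypeMatrix, k: int) -> HaplotypeMatrix:
    """Keep the ``k`` diploid samples with least missing data.

    Haplotype rows are paired (2i, 2i+1) into diploid samples.  Ties in
    missing fraction break by lexicographic sample id.
    """
    if mat.n % 2:
        raise HaplotypeDataError("expected an even number of haplotype rows")
    n_samples = mat.n // 2
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the {n_samples} available samples")
    frac = mat.missing_fraction()
    sample_frac = (frac[0::2] + frac[1::2]) / 2.0
    base_ids = [mat.sample_ids[2 * i] for i in range(n_samples)]
    order = sorted(range(n_samples), key=lambda i: (sample_frac[i], base_ids[i]))
    chosen = sorted(order[:k])
    rows = np.asarray([r for i in chosen for r in (2 * i, 2 * i + 1)])
    return mat.take_haplotypes(rows)
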