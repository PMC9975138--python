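"""Genotype data model, VCF/BED/GFF3 I/O, windowing and LD pruning.

Internal coordinates are 0-based half-open; everything read from or
written to VCF/BED uses the native convention of that format (VCF
1-based, BED 0-based half-open).  The in-memory unit of analysis is the
phased haplotype: a matrix of haplotypes x sites with alleles coded
0 (REF), 1 (ALT) and -1 (missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "SampleTable",
    "SnpWindow",
    "GeneTable",
    "read_vcf",
    "write_vcf",
    "read_sample_table",
    "write_sample_table",
    "windows_by_snp_count",
    "windows_by_bp",
    "pop_allele_freq",
    "ld_prune",
    "read_gene_annotations",
    "merge_haplotypes",
]


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes.

    Attributes
    ----------
    alleles
        int8 array of shape (n_haplotypes, n_sites); 0 = REF, 1 = ALT,
        -1 = missing.  Row ``2*i + j`` is haplotype ``j`` (0 or 1) of
        sample ``i``.
    sample_ids
        One id per diploid sample; each contributes two (possibly
        identical, for inbred lines) haplotype rows.
    chrom, pos, ref, alt
        Per-site chromosome name, 1-based position and REF/ALT alleles.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples (need exactly 2 per sample)"
            )
        n = self.alleles.shape[1]
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("ref", self.ref), ("alt", self.alt)):
            if len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} entries for {n} sites")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def haplotype_labels(self) -> list[tuple[str, int]]:
        """(sample_id, haplotype index) per row."""
        return [(s, j) for s in self.sample_ids for j in (0, 1)]

    def rows_for_samples(self, samples: Iterable[str]) -> np.ndarray:
        """Haplotype row indices for the given sample ids, in order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in samples:
            if s not in index:
                raise KeyError(f"unknown sample id: {s}")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(rows, dtype=np.intp)

    def take_sites(self, idx: np.ndarray | slice) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            alleles=self.alleles[:, idx],
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def take_samples(self, samples: Sequence[str]) -> "HaplotypeMatrix":
        rows = self.rows_for_samples(samples)
        return HaplotypeMatrix(
            alleles=self.alleles[rows, :],
            sample_ids=list(samples),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
        )


def merge_haplotypes(matrices: Sequence[HaplotypeMatrix]) -> HaplotypeMatrix:
    """Stack sample sets that share an identical site frame."""
    first = matrices[0]
    for m in matrices[1:]:
        if not (np.array_equal(m.pos, first.pos)
                and np.array_equal(m.chrom, first.chrom)):
            raise ValueError("matrices do not share the same sites")
    ids: list[str] = []
    for m in matrices:
        for s in m.sample_ids:
            if s in ids:
                raise ValueError(f"duplicate sample id across matrices: {s}")
            ids.append(s)
    return HaplotypeMatrix(
        alleles=np.vstack([m.alleles for m in matrices]),
        sample_ids=ids,
        chrom=first.chrom,
        pos=first.pos,
        ref=first.ref,
        alt=first.alt,
    )


@dataclass
class SampleTable:
    """Sample -> population -> role map (roles: reference/target/outgroup)."""

    df: pd.DataFrame  # columns: sample, population, role

    ROLES = ("reference", "target", "outgroup")

    def __post_init__(self) -> None:
        required = {"sample", "population", "role"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"sample table needs columns {sorted(required)}")
        if self.df["sample"].duplicated().any():
            dup = self.df.loc[self.df["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup}")
        bad = set(self.df["role"]) - set(self.ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "SampleTable":
        return cls(pd.DataFrame(records, columns=["sample", "population", "role"]))

    def samples_in(self, population: str, role: str | None = None) -> list[str]:
        sel = self.df["population"] == population
        if role is not None:
            sel &= self.df["role"] == role
        return self.df.loc[sel, "sample"].tolist()

    @property
    def populations(self) -> list[str]:
        return pd.unique(self.df["population"]).tolist()

    def reference_groups(self) -> dict[str, list[str]]:
        ref = self.df[self.df["role"] == "reference"]
        return {p: g["sample"].tolist() for p, g in ref.groupby("population", sort=True)}

    def targets(self) -> list[str]:
        return self.df.loc[self.df["role"] == "target", "sample"].tolist()


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["sample", "population", "role"], dtype=str)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class SnpWindow:
    """A window of consecutive SNPs: [start_idx, stop_idx) into the site
    axis of a :class:`HaplotypeMatrix`, with 1-based inclusive bp bounds."""

    chrom: str
    start_idx: int
    stop_idx: int
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.stop_idx - self.start_idx

    @property
    def mid_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(
    path: str | Path,
    region: str | None = None,
    allow_unphased: bool = False,
    seed: int | None = None,
) -> HaplotypeMatrix:
    """Read a phased biallelic-SNP VCF into a :class:`HaplotypeMatrix`.

    Multiallelic records and indels are skipped (counted in a warning).
    Unphased heterozygous genotypes are an error unless ``allow_unphased``
    is set, in which case phase is assigned at random using ``seed``.
    """
    from cyvcf2 import VCF

    rchrom, rstart, rend = _parse_region(region)
    rng = np.random.default_rng(seed)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    n_skipped = 0
    for i, v in enumerate(vcf):
        if rchrom is not None:
            if v.CHROM != rchrom:
                continue
            if rstart is not None and v.POS < rstart:
                continue
            if rend is not None and v.POS > rend:
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes
        if gts is None or len(gts) != len(samples):
            raise ValueError(f"record {i + 1} at {v.CHROM}:{v.POS} has no GT field")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for si, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], bool(g[-1])
            if a0 >= 0 and a1 >= 0 and a0 != a1 and not phased:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased heterozygote at {v.CHROM}:{v.POS} sample "
                        f"{samples[si]}; pass allow_unphased=True to randomise phase"
                    )
                if rng.random() < 0.5:
                    a0, a1 = a1, a0
            col[2 * si] = a0 if a0 >= 0 else MISSING
            col[2 * si + 1] = a1 if a1 >= 0 else MISSING
        rows.append(col)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP records in {path}")
    n_sites = len(rows)
    alleles = (np.stack(rows, axis=1) if n_sites
               else np.empty((2 * len(samples), 0), dtype=np.int8))
    return HaplotypeMatrix(
        alleles=alleles,
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def _parse_region(region: str | None) -> tuple[str | None, int | None, int | None]:
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start, end = span.split("-", 1)
    return chrom, int(start), int(end)


def write_vcf(
    matrix: HaplotypeMatrix,
    path: str | Path,
    seed: int | None = None,
    phased: bool = True,
) -> None:
    """Write a phased VCF v4.2.  Missing alleles become '.' within the
    genotype; the header records the writing tool and seed."""
    sep = "|" if phased else "/"
    n = len(matrix.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=introkit(seed={seed})\n")
        for c in pd.unique(matrix.chrom):
            end = int(matrix.pos[matrix.chrom == c].max()) if matrix.n_sites else 0
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j in range(matrix.n_sites):
            col = matrix.alleles[:, j]
            gts = []
            for si in range(n):
                a0, a1 = col[2 * si], col[2 * si + 1]
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                gts.append(f"{s0}{sep}{s1}")
            fh.write(
                f"{matrix.chrom[j]}\t{int(matrix.pos[j])}\t.\t{matrix.ref[j]}\t"
                f"{matrix.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Windowing


def windows_by_snp_count(
    matrix: HaplotypeMatrix, size: int = 150, step: int = 75
) -> list[SnpWindow]:
    """Half-overlapping fixed-SNP-count windows per chromosome.

    Full windows start at indices 0, step, 2*step, ...; if trailing SNPs
    would remain uncovered, one short window from the next step offset to
    the chromosome end is appended provided it holds at least size/2 SNPs.
    Chromosomes with fewer than ``size`` SNPs yield no windows (warning).
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    if not 1 <= step <= size:
        raise ValueError("step must satisfy 1 <= step <= size")
    out: list[SnpWindow] = []
    for c in pd.unique(matrix.chrom):
        idx = np.flatnonzero(matrix.chrom == c)
        lo, S = int(idx[0]), len(idx)
        if S < size:
            warnings.warn(f"chromosome {c} has {S} < {size} SNPs; no windows")
            continue
        n_full = (S - size) // step + 1
        starts = [k * step for k in range(n_full)]
        covered = starts[-1] + size
        if covered < S:
            tail_start = starts[-1] + step
            if S - tail_start >= size / 2:
                starts.append(tail_start)
        for s in starts:
            e = min(s + size, S)
            out.append(SnpWindow(
                chrom=str(c), start_idx=lo + s, stop_idx=lo + e,
                start_bp=int(matrix.pos[lo + s]), end_bp=int(matrix.pos[lo + e - 1]),
            ))
    return out


def windows_by_bp(
    matrix: HaplotypeMatrix, size: int = 100_000, step: int = 50_000,
    anchor: str = "one",
) -> list[SnpWindow]:
    """Sliding physical windows tiling [1, last SNP position] per
    chromosome.  Windows may hold zero SNPs (snp span empty); callers
    filter on SNP count.  ``anchor='data'`` starts the grid at the first
    SNP position instead of bp 1, making the per-window statistics
    invariant to a constant shift of all positions."""
    if size < step:
        raise ValueError("size must be >= step")
    if anchor not in ("one", "data"):
        raise ValueError("anchor must be 'one' or 'data'")
    out: list[SnpWindow] = []
    for c in pd.unique(matrix.chrom):
        idx = np.flatnonzero(matrix.chrom == c)
        pos = matrix.pos[idx]
        chrom_end = int(pos[-1])
        lo = int(idx[0])
        start = 1 if anchor == "one" else int(pos[0])
        starts = []
        while start + size - 1 <= chrom_end:
            starts.append(start)
            start += step
        covered_to = (starts[-1] + size - 1) if starts else 0
        if covered_to < chrom_end:
            starts.append(start)
        for s in starts:
            e = min(s + size - 1, chrom_end)
            i0 = int(np.searchsorted(pos, s, side="left"))
            i1 = int(np.searchsorted(pos, e, side="right"))
            out.append(SnpWindow(chrom=str(c), start_idx=lo + i0, stop_idx=lo + i1,
                                 start_bp=s, end_bp=e))
    return out


# ---------------------------------------------------------------------------
# Frequencies and LD pruning


def pop_allele_freq(
    matrix: HaplotypeMatrix, samples: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ALT frequency and called-haplotype count for a sample set.

    Complete-case per site: frequency = ALT count / non-missing haplotypes.
    Sites where every haplotype is missing get frequency NaN (count 0).
    """
    rows = matrix.rows_for_samples(samples)
    sub = matrix.alleles[rows, :]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    return freq, n_called


def ld_prune(
    matrix: HaplotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy LD pruning in sliding SNP windows (PLINK ``--indep-pairwise``
    style): within each ``window``-SNP span (advancing by ``step``), drop
    the *later* site of any kept pair whose squared allele-dosage Pearson
    correlation exceeds ``r2_max``.  Monomorphic sites never enter a
    correlation and are kept.  The pass repeats on the surviving sites
    until a fixed point, so pruning the pruned set removes nothing.
    Returns sorted kept site indices.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    X = matrix.alleles.astype(np.float64)
    X[X == MISSING] = np.nan
    n_sites = matrix.n_sites
    kept = np.ones(n_sites, dtype=bool)
    while True:
        n_before = int(kept.sum())
        # per-chromosome so windows never span chromosome breaks
        for c in pd.unique(matrix.chrom):
            idx = np.flatnonzero((matrix.chrom == c) & kept)
            start = 0
            while start < len(idx):
                win = idx[start:start + window]
                if len(win) >= 2:
                    _prune_window(X, win, kept, r2_max)
                if start + window >= len(idx):
                    break
                start += step
        if int(kept.sum()) == n_before:
            return np.flatnonzero(kept)


def _prune_window(X: np.ndarray, win: np.ndarray, kept: np.ndarray,
                  r2_max: float) -> None:
    cols = X[:, win]
    # mean-impute the (rare) missing calls for the correlation only
    if np.isnan(cols).any():
        mu = np.nanmean(cols, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        cols = np.where(np.isnan(cols), mu, cols)
    sd = cols.std(axis=0)
    poly = sd > 0
    centred = cols - cols.mean(axis=0)
    for b in range(1, len(win)):
        jb = win[b]
        if not kept[jb] or not poly[b]:
            continue
        for a in range(b):
            ja = win[a]
            if not kept[ja] or not poly[a]:
                continue
            r = centred[:, a] @ centred[:, b] / (len(cols) * sd[a] * sd[b])
            if r * r > r2_max:
                kept[jb] = False
                break


# ---------------------------------------------------------------------------
# Gene annotations


@dataclass
class GeneTable:
    """Gene intervals, 1-based inclusive, sorted by (chrom, start)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "name"]))

    def __post_init__(self) -> None:
        if len(self.df) and (self.df["start"] > self.df["end"]).any():
            raise ValueError("gene interval with start > end")
        self.df = self.df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_gene_annotations(path: str | Path, format: str = "gff3") -> GeneTable:
    """Load gene intervals from GFF3 (``gene`` features only) or BED
    (converted from 0-based half-open to 1-based inclusive)."""
    if format == "gff3":
        return _read_gff3_genes(path)
    if format == "bed":
        return _read_bed_genes(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def _read_gff3_genes(path: str | Path) -> GeneTable:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    records = []
    for g in db.features_of_type("gene"):
        gid = g.id or (g.attributes.get("ID", ["?"])[0])
        name = (g.attributes.get("Name", [gid]) or [gid])[0]
        records.append((gid, g.seqid, int(g.start), int(g.end), name))
    if not records:
        warnings.warn(f"no 'gene' features found in {path}")
        return GeneTable()
    return GeneTable(pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "name"]))


def _read_bed_genes(path: str | Path) -> GeneTable:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1} in {path}")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            rows.append((name, chrom, start0 + 1, end0, name))
    if not rows:
        return GeneTable()
    return GeneTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "name"]))
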