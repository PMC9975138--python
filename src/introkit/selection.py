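"""EHH decay, integrated haplotype homozygosity and the iHS scan.

For a focal biallelic site, EHH(x) is the probability that two
randomly drawn haplotypes carrying the same core allele are identical
over the interval from the focal site out to distance x.  Integrating
EHH over physical distance on both flanks gives iHH per core allele;
iHS = ln(iHH_ref / iHH_alt) is standardised within ALT-frequency bins
(it is approximately standard normal under neutrality) and converted
to a two-sided -log10 p-value via the Gaussian CDF:

    p(iHS) = -log10[ 1 - 2 |Phi(iHS) - 0.5| ]

Sites with -log10 p above a threshold (default 5) are outliers; genes
within a 30 kb flank of any outlier are candidate targets of
selection.  The data are not polarised: the comparison is REF versus
ALT allele, so a negative iHS means the ALT allele carries the
extended haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import MISSING, GeneTable, HaplotypeMatrix

__all__ = [
    "EhhCurve",
    "IhsParams",
    "CandidateGeneHit",
    "ehh_decay",
    "ihh",
    "ihs_unstandardized",
    "ihs_scan",
    "standardize_ihs",
    "ihs_pvalue",
    "call_outliers",
    "candidate_genes",
]


@dataclass
class EhhCurve:
    """EHH values outward from a focal site.

    Each flank is a list of (bp position, EHH) pairs starting at the
    focal site itself (EHH = 1) and extending while EHH >= ehh_min; the
    ``truncated_*`` flags record whether the flank was cut by the decay
    threshold (False means it ran to the chromosome end still above
    threshold)."""

    focal_idx: int
    focal_bp: int
    core_allele: int
    left: list[tuple[int, float]] = field(default_factory=list)
    right: list[tuple[int, float]] = field(default_factory=list)
    truncated_left: bool = False
    truncated_right: bool = False
    n_core: int = 0


@dataclass(frozen=True)
class IhsParams:
    maf_min: float = 0.05
    ehh_min: float = 0.05
    max_gap_bp: float | None = None
    bin_width: float = 0.025
    min_bin: int = 10
    discard_edge_truncated: bool = True
    p_threshold: float = 5.0


@dataclass(frozen=True)
class CandidateGeneHit:
    gene_id: str
    chrom: str
    start: int
    end: int
    name: str
    nearest_snp_bp: int
    distance_bp: int


def ehh_decay(
    matrix: HaplotypeMatrix,
    samples,
    focal_idx: int,
    core_allele: int,
    ehh_min: float = 0.05,
    max_gap_bp: float | None = None,
) -> EhhCurve | None:
    """EHH curve for one core allele at one focal site.

    Haplotypes missing at the focal site are dropped; a missing call on
    the extension path is treated as a private allele (it breaks every
    shared haplotype through it).  Returns None when fewer than two
    haplotypes carry the core allele.
    """
    rows = matrix.rows_for_samples(samples)
    H = matrix.alleles[rows]
    lo, hi = _chrom_bounds(matrix, focal_idx)
    return _ehh_curve(H, matrix.pos, focal_idx, core_allele, lo, hi,
                      ehh_min, max_gap_bp)


def _chrom_bounds(matrix: HaplotypeMatrix, focal_idx: int) -> tuple[int, int]:
    chrom_sites = np.flatnonzero(matrix.chrom == matrix.chrom[focal_idx])
    return int(chrom_sites[0]), int(chrom_sites[-1])


def _ehh_curve(H, pos, focal_idx, core_allele, lo, hi,
               ehh_min, max_gap_bp) -> EhhCurve | None:
    core = np.flatnonzero(H[:, focal_idx] == core_allele)
    if len(core) < 2:
        return None
    curve = EhhCurve(focal_idx=focal_idx, focal_bp=int(pos[focal_idx]),
                     core_allele=core_allele, n_core=len(core))
    core_haps = H[core]
    for direction in (-1, +1):
        pts, truncated = _walk_flank(core_haps, pos, focal_idx, direction,
                                     lo, hi, ehh_min, max_gap_bp)
        if direction < 0:
            curve.left, curve.truncated_left = pts, truncated
        else:
            curve.right, curve.truncated_right = pts, truncated
    return curve


def _walk_flank(core_haps, pos, focal_idx, direction, lo, hi,
                ehh_min, max_gap_bp):
    n = core_haps.shape[0]
    n_pairs = n * (n - 1) // 2
    group = np.zeros(n, dtype=np.int64)
    pts = [(int(pos[focal_idx]), 1.0)]
    j = focal_idx
    prev_bp = pos[focal_idx]
    truncated = False
    while True:
        j += direction
        if j < lo or j > hi:
            break  # chromosome end, still above threshold
        if max_gap_bp is not None and abs(pos[j] - prev_bp) > max_gap_bp:
            truncated = True
            break
        alleles = core_haps[:, j].astype(np.int64)
        # missing extends as a private allele: give it a unique value per hap
        if (alleles == MISSING).any():
            miss = alleles == MISSING
            alleles = alleles.copy()
            alleles[miss] = 2 + np.arange(int(miss.sum()))
        # refine identity groups with the new site
        key = group * (alleles.max() + 1) + alleles
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        ehh = float(np.sum(counts * (counts - 1) // 2) / n_pairs)
        prev_bp = pos[j]
        if ehh < ehh_min:
            truncated = True
            break
        pts.append((int(pos[j]), ehh))
        if ehh == 0.0:
            truncated = True
            break
    return pts, truncated


def ihh(curve: EhhCurve) -> float:
    """Integrated EHH: trapezoidal area under both flanks, in bp * EHH
    units.  A flank holding only the focal point contributes 0."""
    total = 0.0
    for pts in (curve.left, curve.right):
        if len(pts) >= 2:
            bp = np.array([p for p, _ in pts], dtype=np.float64)
            e = np.array([v for _, v in pts], dtype=np.float64)
            total += float(np.abs(np.trapezoid(e, bp)))
    return total


def ihs_unstandardized(
    matrix: HaplotypeMatrix,
    samples,
    focal_idx: int,
    params: IhsParams = IhsParams(),
) -> tuple[float, str]:
    """ln(iHH_ref / iHH_alt) at one site; returns (value, reason) where
    reason is '' on success or a drop code: 'maf' (below the MAF
    filter), 'edge' (a flank hit the chromosome end above the EHH
    threshold), 'zero_ihh', 'mono'."""
    rows = matrix.rows_for_samples(samples)
    H = matrix.alleles[rows]
    lo, hi = _chrom_bounds(matrix, focal_idx)
    return _ihs_site(H, matrix.pos, focal_idx, lo, hi, params)


def _ihs_site(H, pos, focal_idx, lo, hi, params: IhsParams) -> tuple[float, str]:
    col = H[:, focal_idx]
    called = col[col != MISSING]
    if len(called) == 0 or called.min() == called.max():
        return float("nan"), "mono"
    p = float(called.mean())
    if min(p, 1 - p) < params.maf_min:
        return float("nan"), "maf"
    curves = {}
    for allele in (0, 1):
        c = _ehh_curve(H, pos, focal_idx, allele, lo, hi,
                       params.ehh_min, params.max_gap_bp)
        if c is None:
            return float("nan"), "mono"
        if params.discard_edge_truncated and not (c.truncated_left and c.truncated_right):
            return float("nan"), "edge"
        curves[allele] = c
    ihh_ref, ihh_alt = ihh(curves[0]), ihh(curves[1])
    if ihh_ref == 0.0 or ihh_alt == 0.0:
        return float("nan"), "zero_ihh"
    return float(np.log(ihh_ref / ihh_alt)), ""


def ihs_scan(
    matrix: HaplotypeMatrix,
    samples,
    params: IhsParams = IhsParams(),
) -> pd.DataFrame:
    """Genome scan: unstandardised iHS at every eligible site, then
    frequency-bin standardisation and -log10 p-values.  Returns a table
    with one row per site (dropped sites keep their reason code)."""
    rows = matrix.rows_for_samples(samples)
    sub = matrix.alleles[rows]
    called = sub != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(called.sum(axis=0) > 0,
                        np.where(called, sub, 0).sum(axis=0)
                        / np.maximum(called.sum(axis=0), 1), np.nan)
    # chromosome bounds per site, computed once
    bounds: dict[str, tuple[int, int]] = {}
    for c in pd.unique(matrix.chrom):
        sites = np.flatnonzero(matrix.chrom == c)
        bounds[str(c)] = (int(sites[0]), int(sites[-1]))
    records = []
    for j in range(matrix.n_sites):
        lo, hi = bounds[str(matrix.chrom[j])]
        val, reason = _ihs_site(sub, matrix.pos, j, lo, hi, params)
        records.append((matrix.chrom[j], int(matrix.pos[j]), float(freq[j]),
                        val, reason))
    df = pd.DataFrame(records, columns=["chrom", "pos", "alt_freq",
                                        "ihs_raw", "drop_reason"])
    df["ihs"] = standardize_ihs(df["ihs_raw"].to_numpy(),
                                df["alt_freq"].to_numpy(),
                                bin_width=params.bin_width,
                                min_bin=params.min_bin)
    df["neg_log10_p"] = ihs_pvalue(df["ihs"].to_numpy())
    return df


def standardize_ihs(
    ihs_raw: np.ndarray,
    alt_freq: np.ndarray,
    bin_width: float = 0.025,
    min_bin: int = 10,
) -> np.ndarray:
    """Standardise unstandardised iHS within ALT-frequency bins.

    Bins of width ``bin_width`` spanning (0,1); bins holding fewer than
    ``min_bin`` scored sites are merged with their nearest populated
    neighbour.  Within each (merged) bin the scores get the usual
    z-transform; a zero-SD bin maps its sites to 0."""
    out = np.full_like(ihs_raw, np.nan, dtype=np.float64)
    ok = np.isfinite(ihs_raw) & np.isfinite(alt_freq)
    if ok.sum() == 0:
        return out
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    bin_idx = np.clip(np.digitize(alt_freq[ok], edges) - 1, 0, len(edges) - 2)
    bin_idx = _merge_sparse_bins(bin_idx, len(edges) - 1, min_bin)
    vals = ihs_raw[ok]
    z = np.empty_like(vals)
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        mu = vals[sel].mean()
        sd = vals[sel].std(ddof=0)
        z[sel] = 0.0 if sd == 0.0 else (vals[sel] - mu) / sd
    out[ok] = z
    return out


def _merge_sparse_bins(bin_idx: np.ndarray, n_bins: int, min_bin: int) -> np.ndarray:
    """Iteratively remap members of under-filled bins to the nearest
    populated bin until every remaining bin holds >= min_bin sites (or
    only one bin is left)."""
    idx = bin_idx.copy()
    while True:
        counts = np.bincount(idx, minlength=n_bins)
        live = np.flatnonzero(counts > 0)
        if len(live) <= 1:
            return idx
        small = live[counts[live] < min_bin]
        if len(small) == 0:
            return idx
        b = small[np.argmin(counts[small])]
        others = live[live != b]
        target = others[np.argmin(np.abs(others - b))]
        idx[idx == b] = target


def ihs_pvalue(ihs: np.ndarray) -> np.ndarray:
    """Two-sided Gaussian tail transform on the -log10 scale:
    p = -log10[1 - 2 |Phi(iHS) - 0.5|] = -log10(2 * sf(|iHS|))."""
    x = np.abs(np.asarray(ihs, dtype=np.float64))
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.log10(2.0 * norm.sf(x))


def call_outliers(table: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Sites with -log10 p strictly greater than ``threshold``.  Each
    outlier is annotated with its driving allele: 'alt' when iHS < 0
    (extended haplotypes on the ALT allele), 'ref' otherwise."""
    if len(table) == 0:
        return table.assign(driving_allele=pd.Series(dtype=str))
    sig = table[table["neg_log10_p"] > threshold].copy()
    sig["driving_allele"] = np.where(sig["ihs"] < 0, "alt", "ref")
    return sig


def candidate_genes(
    outliers: pd.DataFrame,
    genes: GeneTable,
    flank: int = 30_000,
) -> list[CandidateGeneHit]:
    """Genes whose interval intersects [pos - flank, pos + flank] of any
    outlier SNP, deduplicated, with the nearest outlier's distance
    (0 when a SNP lies inside the gene)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, snp in outliers.iterrows():
        trees.setdefault(snp["chrom"], IntervalTree()).addi(
            snp["pos"] - flank, snp["pos"] + flank + 1, int(snp["pos"]))
    hits: dict[str, CandidateGeneHit] = {}
    for _, g in genes.df.iterrows():
        tree = trees.get(g["chrom"])
        if tree is None:
            continue
        best = None
        for iv in tree.overlap(g["start"], g["end"] + 1):
            snp_bp = iv.data
            if g["start"] <= snp_bp <= g["end"]:
                d = 0
            else:
                d = min(abs(snp_bp - g["start"]), abs(snp_bp - g["end"]))
            if best is None or d < best[1]:
                best = (snp_bp, d)
        if best is not None and g["gene_id"] not in hits:
            hits[g["gene_id"]] = CandidateGeneHit(
                gene_id=g["gene_id"], chrom=g["chrom"],
                start=int(g["start"]), end=int(g["end"]), name=g["name"],
                nearest_snp_bp=best[0], distance_bp=best[1])
    return list(hits.values())
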