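"""Frequency-based ABBA-BABA introgression tests.

Patterson's D compares the counts of the two discordant site patterns
in a four-taxon tree (((P1,P2),P3),P4): an excess of ABBA over BABA
indicates gene flow between P3 and P2, an excess of BABA gene flow
between P3 and P1.  With population samples the per-site pattern
counts are replaced by their frequency expectations (Durand et al.):

    ABBA = (1-p1) * p2 * p3 * (1-p4)
    BABA = p1 * (1-p2) * p3 * (1-p4)

    D = [sum(ABBA) - sum(BABA)] / sum(ABBA + BABA)

Standard errors come from a delete-one block jackknife over contiguous
equal-SNP-count blocks; |Z| > 3 is the conventional significance rule.
The admixture proportion f-hat and the windowed fd / fdM statistics
substitute a donor frequency into the denominator following the
approach of S. Martin's genomics_general scripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import HaplotypeMatrix, SampleTable, SnpWindow, pop_allele_freq

__all__ = [
    "QuartetFreqs",
    "QuartetResult",
    "quartet_freqs",
    "site_patterns",
    "d_statistic",
    "block_jackknife",
    "jackknife_from_block_sums",
    "admixture_fraction_f",
    "fd_fdM_windows",
    "dstat",
]


@dataclass
class QuartetFreqs:
    """Per-site ALT frequencies for the four populations of a quartet.
    A site is usable iff all four frequencies are defined."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    usable: np.ndarray = field(default=None)  # type: ignore[assignment]
    n3: np.ndarray | None = None  # called-haplotype count in P3, for f-hat

    def __post_init__(self) -> None:
        if self.usable is None:
            self.usable = ~(np.isnan(self.p1) | np.isnan(self.p2)
                            | np.isnan(self.p3) | np.isnan(self.p4))

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def swap_p1_p2(self) -> "QuartetFreqs":
        return QuartetFreqs(p1=self.p2, p2=self.p1, p3=self.p3, p4=self.p4,
                            chrom=self.chrom, pos=self.pos, usable=self.usable,
                            n3=self.n3)


@dataclass
class QuartetResult:
    """Genome-level ABBA-BABA summary."""

    sum_abba: float
    sum_baba: float
    D: float
    SE: float
    Z: float
    n_blocks: int
    f_hat: float
    n_sites: int
    windows: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        """Conventional rule: gene flow supported when |Z| > 3."""
        return abs(self.Z) > 3.0


def quartet_freqs(
    matrix: HaplotypeMatrix,
    samples: SampleTable,
    p1: str, p2: str, p3: str, p4: str,
) -> QuartetFreqs:
    """Compute per-site frequencies for the four named populations."""
    freqs, counts = [], []
    for pop in (p1, p2, p3, p4):
        ids = samples.samples_in(pop)
        if not ids:
            raise ValueError(f"population {pop!r} absent from sample table")
        f, n = pop_allele_freq(matrix, ids)
        freqs.append(f)
        counts.append(n)
    return QuartetFreqs(p1=freqs[0], p2=freqs[1], p3=freqs[2], p4=freqs[3],
                        chrom=matrix.chrom, pos=matrix.pos, n3=counts[2])


def site_patterns(freqs: QuartetFreqs) -> tuple[np.ndarray, np.ndarray]:
    """Per-usable-site frequency weights (ABBA, BABA)."""
    u = freqs.usable
    p1, p2, p3, p4 = freqs.p1[u], freqs.p2[u], freqs.p3[u], freqs.p4[u]
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def d_statistic(abba: np.ndarray, baba: np.ndarray) -> float:
    """D = [sum(ABBA) - sum(BABA)] / sum(ABBA + BABA); NaN when the
    denominator is zero (undefined, deliberately not 0)."""
    sa, sb = float(np.sum(abba)), float(np.sum(baba))
    denom = sa + sb
    if denom == 0.0:
        return float("nan")
    return (sa - sb) / denom


def block_jackknife(
    abba: np.ndarray, baba: np.ndarray, n_blocks: int = 379
) -> tuple[float, float]:
    """Delete-one block jackknife over contiguous equal-SNP-count blocks.

    Returns (SE, Z) for the D statistic.  SE uses the standard jackknife
    variance sqrt((m-1)/m * sum((D_-i - mean)^2)); Z = D / SE.  When
    SE = 0 with D != 0, Z is reported as +/-inf with a warning.
    """
    if n_blocks < 20:
        raise ValueError("n_blocks must be >= 20")
    if len(abba) < n_blocks:
        raise ValueError(f"{len(abba)} usable sites < {n_blocks} blocks")
    a_blocks = np.array([b.sum() for b in np.array_split(abba, n_blocks)])
    b_blocks = np.array([b.sum() for b in np.array_split(baba, n_blocks)])
    _, se, z = jackknife_from_block_sums(a_blocks, b_blocks)
    return se, z


def jackknife_from_block_sums(
    a_blocks: np.ndarray, b_blocks: np.ndarray
) -> tuple[float, float, float]:
    """Delete-one jackknife of D from per-block (ABBA, BABA) sums.
    Returns (D, SE, Z)."""
    a_blocks = np.asarray(a_blocks, dtype=float)
    b_blocks = np.asarray(b_blocks, dtype=float)
    sa, sb = a_blocks.sum(), b_blocks.sum()
    d_full = d_statistic(a_blocks, b_blocks)
    num = (sa - a_blocks) - (sb - b_blocks)
    den = (sa - a_blocks) + (sb - b_blocks)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_del = num / den
    if np.isnan(d_del).any():
        raise ValueError("a delete-one replicate has zero ABBA+BABA mass")
    m = len(a_blocks)
    se = float(np.sqrt((m - 1) / m * np.sum((d_del - d_del.mean()) ** 2)))
    if se == 0.0:
        if d_full != 0.0:
            warnings.warn("jackknife SE is 0 with D != 0; Z reported as inf")
            return d_full, se, float(np.sign(d_full) * np.inf)
        return d_full, se, 0.0
    return d_full, se, d_full / se


def admixture_fraction_f(freqs: QuartetFreqs) -> float:
    """Admixture proportion f-hat = S(P1,P2,P3,P4) / S(P1,P3,P3,P4),
    where S is the ABBA-BABA numerator sum with the named populations in
    the four slots (the donor P3 standing in for P2 in the denominator).

    The denominator's p3*p3 product uses the unbiased estimator of the
    squared population frequency, p^2 - p(1-p)/(n-1) with n the called
    P3 haplotype count, so that complete replacement of P2 by the donor
    pool yields f-hat ~ 1 rather than a value depressed by the sampling
    variance of p3.  Values outside [0,1] are returned unchanged with a
    warning."""
    u = freqs.usable
    p1, p2, p3, p4 = freqs.p1[u], freqs.p2[u], freqs.p3[u], freqs.p4[u]
    num = np.sum((1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4))
    if freqs.n3 is not None:
        n3 = freqs.n3[u].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p33 = np.where(n3 > 1, p3**2 - p3 * (1 - p3) / np.maximum(n3 - 1, 1),
                           p3**2)
    else:
        p33 = p3**2
    den = np.sum((1 - p4) * (p33 - p1 * p3))
    if den == 0.0:
        return float("nan")
    f = float(num / den)
    if not 0.0 <= f <= 1.0:
        warnings.warn(f"f-hat = {f:.4f} outside [0,1]; reported unchanged")
    return f


def fd_fdM_windows(
    freqs: QuartetFreqs,
    windows: list[SnpWindow],
    min_sites: int = 20,
) -> pd.DataFrame:
    """Windowed D, fd and fdM.

    fd substitutes the dynamic donor pD = max(p2, p3) per site into both
    the P2 and P3 slots of the denominator; it is reported only where
    the window D >= 0 (NaN otherwise).  fdM extends fd symmetrically:
    for windows with D < 0 the denominator substitutes pD = max(p1, p3)
    into the P1 and P3 slots and the statistic is negated, so positive
    fdM means introgression P3 -> P2 and negative P3 -> P1.
    """
    rows = []
    for w in windows:
        sl = slice(w.start_idx, w.stop_idx)
        u = freqs.usable[sl]
        p1 = freqs.p1[sl][u]
        p2 = freqs.p2[sl][u]
        p3 = freqs.p3[sl][u]
        p4 = freqs.p4[sl][u]
        n_sites = len(p1)
        if n_sites < min_sites:
            rows.append((w.chrom, w.start_bp, w.end_bp, n_sites,
                         np.nan, np.nan, np.nan, True))
            continue
        num = np.sum(_s(p1, p2, p3, p4))
        denom_total = np.sum((1 - p1) * p2 * p3 * (1 - p4)
                             + p1 * (1 - p2) * p3 * (1 - p4))
        d = num / denom_total if denom_total > 0 else np.nan
        pd23 = np.maximum(p2, p3)
        den_fd = np.sum(_s(p1, pd23, pd23, p4))
        fd = (num / den_fd if (not np.isnan(d) and d >= 0 and den_fd != 0)
              else np.nan)
        if np.isnan(d):
            fdm = np.nan
        elif d >= 0:
            fdm = num / den_fd if den_fd != 0 else np.nan
        else:
            pd13 = np.maximum(p1, p3)
            den_m = np.sum(_s(pd13, p2, pd13, p4))
            fdm = -(num / den_m) if den_m != 0 else np.nan
        rows.append((w.chrom, w.start_bp, w.end_bp, n_sites, d, fd, fdm, False))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_sites", "D", "fd", "fdM", "excluded"])


def _s(p1, p2, p3, p4):
    """Per-site ABBA - BABA numerator."""
    return (1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)


def dstat(
    matrix: HaplotypeMatrix,
    samples: SampleTable,
    p1: str, p2: str, p3: str, p4: str,
    n_blocks: int = 379,
    windows: list[SnpWindow] | None = None,
) -> QuartetResult:
    """Full ABBA-BABA analysis: D, jackknife SE/Z, f-hat, and optional
    windowed fd / fdM."""
    freqs = quartet_freqs(matrix, samples, p1, p2, p3, p4)
    abba, baba = site_patterns(freqs)
    d = d_statistic(abba, baba)
    se, z = block_jackknife(abba, baba, n_blocks=n_blocks)
    f = admixture_fraction_f(freqs)
    win_df = fd_fdM_windows(freqs, windows) if windows is not None else None
    return QuartetResult(
        sum_abba=float(abba.sum()), sum_baba=float(baba.sum()),
        D=d, SE=se, Z=z, n_blocks=n_blocks, f_hat=f,
        n_sites=freqs.n_usable, windows=win_df)
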