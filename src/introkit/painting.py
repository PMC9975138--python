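"""Supervised chromosome painting by windowed PCA and kernel density
classification.

Each 150-SNP half-overlapping window is reduced by PCA (fitted jointly
on reference and target haplotypes), a Gaussian product-kernel density
is fitted per reference group on the first five components, and every
target haplotype is assigned the label whose posterior (equal-prior
normalised density) clears the thresholds:

* single group if its posterior >= 0.8,
* the top-two pair (a "shared" label, e.g. ``japonica+aus``) if their
  joint posterior >= 0.8 and each >= 0.1,
* ``unspecific`` otherwise,
* ``absent`` when the window cannot support the classifier (too few
  polymorphic sites, a reference group below 5 haplotypes, or more
  than half of the group's calls missing).

Overlapping windows are reconciled per step-sized slice by keeping the
covering window with the larger top posterior; runs of equal labels
merge into ideogram tracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .genio import MISSING, HaplotypeMatrix, SampleTable, SnpWindow, windows_by_snp_count
from .simulate import TruthSet

__all__ = [
    "PaintingConfig",
    "WindowAssignment",
    "PaintedTrack",
    "GaussianProductKDE",
    "select_references",
    "fit_window_pca",
    "fit_reference_kde",
    "assign_haplotype",
    "paint_genome",
    "evaluate_painting",
    "PaintingReport",
]

UNSPECIFIC = "unspecific"
ABSENT = "absent"


@dataclass(frozen=True)
class PaintingConfig:
    window_size: int = 150
    window_step: int = 75
    n_pcs: int = 5
    single_label_min_posterior: float = 0.8
    dual_label_min_joint: float = 0.8
    dual_label_min_each: float = 0.1
    absent_max_missing_fraction: float = 0.5
    min_group_haplotypes: int = 5
    bandwidth_floor: float = 1e-3

    def __post_init__(self) -> None:
        for t in (self.single_label_min_posterior, self.dual_label_min_joint,
                  self.dual_label_min_each, self.absent_max_missing_fraction):
            if not 0.0 < t <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.window_step > self.window_size:
            raise ValueError("window_step must be <= window_size")


@dataclass
class WindowAssignment:
    window: SnpWindow
    sample: str
    hap: int
    label: str
    posteriors: dict[str, float] | None

    @property
    def top_posterior(self) -> float:
        if not self.posteriors:
            return -1.0
        return max(self.posteriors.values())


@dataclass
class PaintedTrack:
    """Per-haplotype painting on one chromosome: an ordered sequence of
    step-sized slice labels and the merged ideogram tracts."""

    sample: str
    hap: int
    chrom: str
    slice_labels: list[str]
    slice_bounds: list[tuple[int, int]]  # 1-based inclusive bp per slice
    tracts: list[tuple[str, int, int, str]]  # (chrom, start_bp, end_bp, label)


def select_references(
    props: pd.DataFrame, cutoff: float = 0.8
) -> SampleTable:
    """Assign reference/target roles from a global ancestry-proportion
    table (index = sample, one column per cluster).

    A sample is a reference for cluster c iff its fraction for c is
    >= cutoff (inclusive); anything below every cutoff is an admixed
    target.  Cutoffs <= 0.5 would allow double assignment and are
    rejected."""
    if cutoff <= 0.5:
        raise ValueError("cutoff must exceed 0.5 to guarantee a unique assignment")
    sums = props.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = props.index[~np.isclose(sums, 1.0, atol=1e-6)][0]
        raise ValueError(f"ancestry fractions for {bad!r} do not sum to 1")
    records = []
    for sample, row in props.iterrows():
        top = row.idxmax()
        if row[top] >= cutoff:
            records.append((str(sample), str(top), "reference"))
        else:
            records.append((str(sample), "admixed", "target"))
    return SampleTable.from_records(records)


def fit_window_pca(
    window_alleles: np.ndarray, n_pcs: int = 5
) -> np.ndarray | None:
    """PCA coordinates (haplotypes x n_pcs) for one window's allele
    slice.  Missing alleles are mean-imputed per site, sites are
    mean-centred, components are ordered by decreasing variance with
    the largest-magnitude loading made positive.  Returns None when the
    window has fewer than n_pcs + 1 polymorphic sites (flagged absent
    by the caller)."""
    X = window_alleles.astype(np.float64)
    miss = X == MISSING
    if miss.any():
        X[miss] = np.nan
        mu = np.nanmean(X, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        X = np.where(np.isnan(X), mu, X)
    poly = X.std(axis=0) > 0
    if int(poly.sum()) < n_pcs + 1:
        return None
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_pcs):
        load = pca.components_[k]
        j = int(np.argmax(np.abs(load)))
        if load[j] < 0:
            coords[:, k] *= -1.0
    return coords


class GaussianProductKDE:
    """Parzen-Rosenblatt estimator with a diagonal (per-dimension)
    Gaussian kernel; bandwidths follow Scott's rule
    sigma_d * m**(-1/(d+4)), floored to keep zero-variance dimensions
    evaluable."""

    def __init__(self, points: np.ndarray, bandwidth_floor: float = 1e-3):
        self.points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        m, d = self.points.shape
        sigma = self.points.std(axis=0, ddof=1) if m > 1 else np.zeros(d)
        self.bandwidth = np.maximum(sigma * m ** (-1.0 / (d + 4)), bandwidth_floor)
        self._log_norm = np.sum(np.log(self.bandwidth * np.sqrt(2.0 * np.pi)))

    def logpdf(self, x: np.ndarray) -> float:
        z = (np.asarray(x, dtype=np.float64) - self.points) / self.bandwidth
        log_k = -0.5 * np.sum(z * z, axis=1) - self._log_norm
        return float(logsumexp(log_k) - np.log(len(self.points)))

    def pdf(self, x: np.ndarray) -> float:
        return float(np.exp(self.logpdf(x)))


def fit_reference_kde(
    coords: np.ndarray,
    groups: dict[str, np.ndarray],
    config: PaintingConfig = PaintingConfig(),
) -> dict[str, GaussianProductKDE | None]:
    """One KDE per reference group over its haplotypes' PC coordinates.
    Groups with fewer than ``min_group_haplotypes`` members are flagged
    absent (None)."""
    kdes: dict[str, GaussianProductKDE | None] = {}
    for name, rows in groups.items():
        if len(rows) < config.min_group_haplotypes:
            kdes[name] = None
        else:
            kdes[name] = GaussianProductKDE(coords[rows],
                                            bandwidth_floor=config.bandwidth_floor)
    return kdes


def assign_haplotype(
    point: np.ndarray,
    kdes: dict[str, GaussianProductKDE | None],
    config: PaintingConfig = PaintingConfig(),
) -> tuple[str, dict[str, float] | None]:
    """Label one haplotype's window coordinates against the reference
    densities.  Posteriors are equal-prior normalised densities; the
    label rules are described in the module docstring."""
    live = {g: k for g, k in kdes.items() if k is not None}
    if len(live) < 2:
        return ABSENT, None
    names = sorted(live)
    logd = np.array([live[g].logpdf(point) for g in names])
    if not np.any(np.isfinite(logd)):
        return UNSPECIFIC, {g: 1.0 / len(names) for g in names}
    post = np.exp(logd - logsumexp(logd))
    posteriors = {g: float(p) for g, p in zip(names, post)}
    order = np.argsort(post)[::-1]
    top, second = order[0], order[1] if len(order) > 1 else order[0]
    if post[top] >= config.single_label_min_posterior:
        return names[top], posteriors
    joint = post[top] + post[second]
    if (joint >= config.dual_label_min_joint
            and post[top] >= config.dual_label_min_each
            and post[second] >= config.dual_label_min_each):
        pair = sorted([names[top], names[second]])
        return f"{pair[0]}+{pair[1]}", posteriors
    return UNSPECIFIC, posteriors


def paint_genome(
    matrix: HaplotypeMatrix,
    samples: SampleTable,
    config: PaintingConfig = PaintingConfig(),
) -> list[PaintedTrack]:
    """Paint every target haplotype across all windows and merge into
    ideogram tracts."""
    groups_samples = samples.reference_groups()
    if len(groups_samples) < 2:
        raise ValueError("painting needs reference samples from >= 2 groups")
    group_rows = {g: matrix.rows_for_samples(ids)
                  for g, ids in groups_samples.items()}
    target_samples = samples.targets()
    target_rows = matrix.rows_for_samples(target_samples)
    target_labels = [(s, j) for s in target_samples for j in (0, 1)]

    windows = windows_by_snp_count(matrix, config.window_size, config.window_step)
    if not windows:
        warnings.warn("no paintable windows; returning empty tracks")
        return []

    # per-window assignment for each target haplotype
    assignments: dict[SnpWindow, list[WindowAssignment]] = {}
    for w in windows:
        sl = matrix.alleles[:, w.start_idx:w.stop_idx]
        coords = fit_window_pca(sl, config.n_pcs)
        if coords is None:
            assignments[w] = [WindowAssignment(w, s, h, ABSENT, None)
                              for s, h in target_labels]
            continue
        kdes = _window_kdes(sl, coords, group_rows, config)
        out = []
        for (s, h), row in zip(target_labels, target_rows):
            label, post = assign_haplotype(coords[row], kdes, config)
            out.append(WindowAssignment(w, s, h, label, post))
        assignments[w] = out

    return _merge_tracks(matrix, windows, assignments, target_labels, config)


def _window_kdes(window_alleles, coords, group_rows, config):
    kdes = {}
    for g, rows in group_rows.items():
        sub = window_alleles[rows]
        missing_frac = float((sub == MISSING).mean())
        if missing_frac > config.absent_max_missing_fraction:
            kdes[g] = None
        elif len(rows) < config.min_group_haplotypes:
            kdes[g] = None
        else:
            kdes[g] = GaussianProductKDE(coords[rows],
                                         bandwidth_floor=config.bandwidth_floor)
    return kdes


def _merge_tracks(matrix, windows, assignments, target_labels, config):
    step = config.window_step
    tracks: list[PaintedTrack] = []
    by_chrom: dict[str, list[SnpWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    for chrom, wins in by_chrom.items():
        idx = np.flatnonzero(matrix.chrom == chrom)
        lo, S = int(idx[0]), len(idx)
        n_slices = (S + step - 1) // step
        slice_spans = [(k * step, min((k + 1) * step, S)) for k in range(n_slices)]
        # covering window per slice, chosen later per haplotype by posterior
        cover = [[w for w in wins
                  if w.start_idx - lo <= a and w.stop_idx - lo >= b]
                 for a, b in slice_spans]
        for t_i, (s, h) in enumerate(target_labels):
            labels: list[str] = []
            bounds: list[tuple[int, int]] = []
            for (a, b), wcands in zip(slice_spans, cover):
                best_label, best_post, best_start = ABSENT, -2.0, None
                for w in wcands:
                    asg = assignments[w][t_i]
                    p = asg.top_posterior
                    if p > best_post or (p == best_post and
                                         (best_start is None or w.start_idx < best_start)):
                        best_label, best_post, best_start = asg.label, p, w.start_idx
                if not wcands:
                    best_label = ABSENT
                labels.append(best_label)
                bounds.append((int(matrix.pos[lo + a]), int(matrix.pos[lo + b - 1])))
            tracks.append(PaintedTrack(
                sample=s, hap=h, chrom=chrom,
                slice_labels=labels, slice_bounds=bounds,
                tracts=_runs_to_tracts(chrom, labels, bounds)))
    return tracks


def _runs_to_tracts(chrom, labels, bounds):
    tracts = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            tracts.append((chrom, bounds[start][0], bounds[i - 1][1], labels[start]))
            start = i
    return tracts


@dataclass
class PaintingReport:
    accuracy: float
    n_slices: int
    boundary_errors_bp: list[tuple[float, float]]
    confusion: pd.DataFrame
    all_unspecific: bool = False


def evaluate_painting(
    tracks: list[PaintedTrack],
    truth: TruthSet,
    background_pop: str,
) -> PaintingReport:
    """Score painted tracks against the generator's truth.

    A slice is correct iff its label equals — or, for a dual label,
    contains — the true ancestry at the slice midpoint (the donor of a
    covering truth tract, otherwise the background population).  For
    each truth tract the boundary error of the longest overlapping
    donor-labelled painted tract is reported per side (inf when the
    tract was missed entirely)."""
    known = {(s, h) for s, h, _ in truth.tracts}
    painted = {(t.sample, t.hap) for t in tracks}
    orphan = known - painted
    if orphan:
        raise ValueError(f"truth tracts for unpainted haplotypes: {sorted(orphan)}")

    n_correct = n_total = 0
    counts: dict[tuple[str, str], int] = {}
    for t in tracks:
        for label, (a, b) in zip(t.slice_labels, t.slice_bounds):
            mid = 0.5 * (a + b)
            hit = truth.tract_at(t.sample, t.hap, t.chrom, mid)
            expected = hit.donor_pop if hit else background_pop
            ok = label == expected or expected in label.split("+")
            n_correct += ok
            n_total += 1
            counts[(expected, label)] = counts.get((expected, label), 0) + 1
    confusion = (pd.Series(counts).rename_axis(["truth", "label"])
                 .unstack(fill_value=0) if counts else pd.DataFrame())

    boundary: list[tuple[float, float]] = []
    for s, h, spec in truth.tracts:
        best = None
        for t in tracks:
            if (t.sample, t.hap) != (s, h) or t.chrom != spec.chrom:
                continue
            for chrom, a, b, label in t.tracts:
                if label == spec.donor_pop and a <= spec.end_bp and b >= spec.start_bp:
                    if best is None or (b - a) > (best[1] - best[0]):
                        best = (a, b)
        if best is None:
            boundary.append((float("inf"), float("inf")))
        else:
            boundary.append((abs(best[0] - spec.start_bp), abs(best[1] - spec.end_bp)))

    accuracy = n_correct / n_total if n_total else 0.0
    labels_seen = {lab for t in tracks for lab in t.slice_labels}
    return PaintingReport(
        accuracy=accuracy, n_slices=n_total, boundary_errors_bp=boundary,
        confusion=confusion, all_unspecific=labels_seen <= {UNSPECIFIC, ABSENT})
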