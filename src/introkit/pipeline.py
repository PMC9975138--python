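"""End-to-end orchestration: input validation and the synthetic demo.

The demo reproduces the full inference chain on generated data with
known truth — paint an admixed cohort against three reference pools,
test the quartet for gene flow (null and f = 0.2), localise the
planted tract with windowed Fst and fdM, and recover a founder-copy
sweep with the iHS scan — and reports pass/fail for each recovery
check.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abba, painting, selection, simulate, windows
from .genio import (
    GeneTable,
    HaplotypeMatrix,
    SampleTable,
    read_sample_table,
    read_vcf,
    windows_by_bp,
)

__all__ = ["validate_inputs", "run_demo", "DemoReport", "Diagnostics"]


@dataclass
class Diagnostics:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    haplotype_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(
    vcf_path: str | Path,
    pops_path: str | Path,
    genes_path: str | Path | None = None,
) -> Diagnostics:
    """Check phasing, biallelicity, sorted positions and population
    coverage before a run; fatal findings abort the pipeline."""
    diag = Diagnostics()
    try:
        matrix = read_vcf(vcf_path)
    except ValueError as exc:
        diag.fatal.append(f"VCF: {exc}")
        return diag
    table = read_sample_table(pops_path)
    vcf_samples = set(matrix.sample_ids)
    missing = [s for s in table.df["sample"] if s not in vcf_samples]
    if missing:
        diag.fatal.append(f"samples in table absent from VCF: {missing[:5]}")
    extra = vcf_samples - set(table.df["sample"])
    if extra:
        diag.warnings.append(f"{len(extra)} VCF samples not in the table")
    for pop in table.populations:
        n = 2 * len([s for s in table.samples_in(pop) if s in vcf_samples])
        diag.haplotype_counts[pop] = n
        if n == 0:
            diag.fatal.append(f"population {pop!r} has no samples in the VCF")
    if genes_path is not None:
        from .genio import read_gene_annotations

        fmt = "bed" if str(genes_path).endswith(".bed") else "gff3"
        genes = read_gene_annotations(genes_path, format=fmt)
        if len(genes) == 0:
            diag.warnings.append("gene annotation file yields no genes")
    return diag


@dataclass
class DemoReport:
    checks: dict[str, bool] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    elapsed_s: float = 0.0

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"passed": bool(self.ok),
             "checks": {k: bool(v) for k, v in self.checks.items()},
             "metrics": {k: float(v) for k, v in self.metrics.items()},
             "elapsed_s": round(self.elapsed_s, 1)},
            indent=2))


def run_demo(outdir: str | Path, seed: int = 0) -> DemoReport:
    """Run the full synthetic chain and score every stage against its
    generator truth.  Writes the painted-track ideogram, stage tables
    and a JSON report into ``outdir``."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = DemoReport()
    rng = np.random.default_rng(seed)

    # --- painting recovery -------------------------------------------------
    matrix, table, truth = simulate.painting_scenario(seed=seed)
    tracks = painting.paint_genome(matrix, table)
    ev = painting.evaluate_painting(tracks, truth, background_pop="japonica")
    step_bp = 75 * simulate.DEFAULT_BP_PER_SITE
    max_err = max((max(a, b) for a, b in ev.boundary_errors_bp), default=0.0)
    report.metrics["painting_accuracy"] = ev.accuracy
    report.metrics["painting_max_boundary_error_bp"] = max_err
    report.checks["painting_accuracy>=0.90"] = ev.accuracy >= 0.90
    report.checks["painting_boundary<=1_step"] = max_err <= step_bp
    from .plotting import render_ideogram

    render_ideogram(tracks, outdir / "ideogram.png",
                    group_names=["japonica", "indica", "aus"])

    # --- windowed-scan localisation of the planted tract -------------------
    tract = truth.tracts[0][2]
    carriers = truth.carrier_samples()
    non_carriers = [s for s in table.targets() if s not in carriers]
    split = SampleTable.from_records(
        [(s, "carrier", "target") for s in carriers]
        + [(s, "noncarrier", "target") for s in non_carriers])
    scan = windows.sliding_scan(matrix.take_samples(split.df["sample"].tolist()),
                                split)
    scan.to_csv(outdir / "window_stats.tsv", sep="\t", index=False)
    live = scan[~scan["excluded"]]
    top_fst = live.loc[live["fst_carrier__noncarrier"].idxmax()]
    fst_hit = (top_fst["start_bp"] <= tract.end_bp
               and top_fst["end_bp"] >= tract.start_bp)
    report.metrics["max_fst_window_start"] = float(top_fst["start_bp"])
    report.checks["max_fst_window_overlaps_tract"] = bool(fst_hit)

    # --- quartet D / f-hat -------------------------------------------------
    for f_true, tag in ((0.0, "null"), (0.2, "admixed")):
        qmatrix, qtable, _ = simulate.quartet_scenario(
            f_true, seed=int(rng.integers(2**31)))
        bp_wins = windows_by_bp(qmatrix)
        res = abba.dstat(qmatrix, qtable, "P1", "P2", "P3", "P4",
                         windows=bp_wins)
        report.metrics[f"quartet_{tag}_D"] = res.D
        report.metrics[f"quartet_{tag}_Z"] = res.Z
        report.metrics[f"quartet_{tag}_f_hat"] = res.f_hat
        if tag == "null":
            report.checks["quartet_null_|Z|<3"] = abs(res.Z) < 3
        else:
            report.checks["quartet_admixed_Z>3"] = res.Z > 3
            report.checks["quartet_admixed_f_hat_in_[0.1,0.3]"] = 0.1 <= res.f_hat <= 0.3

    # fdM localisation on the painting scenario's quartet analogue:
    # carriers as P2, non-carriers as P1, donor pool as P3, indica as P4
    quartet_like = SampleTable.from_records(
        [(s, "P1", "reference") for s in non_carriers]
        + [(s, "P2", "target") for s in carriers]
        + [(s, "P3", "reference") for s in table.samples_in("aus")]
        + [(s, "P4", "outgroup") for s in table.samples_in("indica")])
    freqs = abba.quartet_freqs(matrix, quartet_like, "P1", "P2", "P3", "P4")
    fdm = abba.fd_fdM_windows(freqs, windows_by_bp(matrix))
    top_fdm = fdm.loc[fdm["fdM"].idxmax()]
    fdm_hit = (top_fdm["start_bp"] <= tract.end_bp
               and top_fdm["end_bp"] >= tract.start_bp)
    report.checks["max_fdM_window_overlaps_tract"] = bool(fdm_hit)

    # --- iHS sweep recovery ------------------------------------------------
    smatrix, stable, struth = simulate.sweep_scenario(seed=seed)
    ihs = selection.ihs_scan(smatrix, stable.df["sample"].tolist())
    ihs.to_csv(outdir / "ihs_scan.tsv", sep="\t", index=False)
    scored = ihs.dropna(subset=["ihs"])
    peak = scored.loc[scored["ihs"].abs().idxmax()]
    dist = abs(peak["pos"] - struth.sweep.focal_bp)
    report.metrics["sweep_peak_distance_bp"] = float(dist)
    report.metrics["sweep_peak_neg_log10_p"] = float(peak["neg_log10_p"])
    # the sweep signal spans the swept tract: the 500 kb copied region
    # broadened by the exponential tails (2 * mean tract length covers
    # ~86% of carrier boundaries)
    footprint = 250_000 + 2 * struth.sweep.mean_tract_bp
    report.checks["sweep_peak_within_swept_footprint"] = dist <= footprint
    report.checks["sweep_peak_p>5"] = peak["neg_log10_p"] > 5

    # candidate genes around the sweep peak, against a small synthetic
    # gene table spanning the region
    gene_rows = [(f"gene_{k:03d}", "chr1", s, s + 20_000, f"gene_{k:03d}")
                 for k, s in enumerate(range(1, 5_000_000, 100_000))]
    genes = GeneTable(pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "name"]))
    outliers = selection.call_outliers(ihs)
    hits = selection.candidate_genes(outliers, genes)
    report.metrics["n_ihs_outliers"] = float(len(outliers))
    report.metrics["n_candidate_genes"] = float(len(hits))
    report.checks["candidate_genes_nonempty"] = len(hits) > 0

    report.elapsed_s = time.time() - t0
    report.to_json(outdir / "demo_report.json")
    return report
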