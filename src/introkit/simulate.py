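"""Seeded synthetic genotype scenarios with machine-readable truth.

The generator emulates the statistical structure that the downstream
inference assumes, at desk scale:

* three strongly diverged reference gene pools plus a distant outgroup
  lineage, drawn from a Balding-Nichols drift model (population allele
  frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
  frequency p),
* admixed target genomes that are background-pool mosaics carrying
  contiguous donor tracts (the hallmark of recent introgression in a
  selfing crop),
* four-taxon (P1,P2,P3,P4) gene-flow scenarios with a tunable
  introgressed fraction laid down in contiguous blocks,
* partial selective sweeps built by copying a founder haplotype
  outward from a focal allele for exponentially distributed distances,
  which creates the extended haplotype homozygosity that iHS detects.

Sites are statistically independent (no background LD) except inside
sweep regions and planted tracts; the frequency-based statistics
downstream only require LD where the haplotype-based scan needs it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import HaplotypeMatrix, SampleTable, write_sample_table, write_vcf

__all__ = [
    "PopModel",
    "TractSpec",
    "SweepSpec",
    "TruthSet",
    "simulate_reference_panels",
    "simulate_admixed_targets",
    "simulate_quartet",
    "simulate_sweep_region",
    "emit_dataset",
    "painting_scenario",
    "quartet_scenario",
    "sweep_scenario",
]

DEFAULT_CHROM = "chr1"
DEFAULT_BP_PER_SITE = 1_000  # 1 SNP per kb on a 30 Mb pseudo-chromosome


@dataclass(frozen=True)
class PopModel:
    """Balding-Nichols panel description: one drift coefficient F and a
    haplotype count per population, sharing one ancestral frequency
    distribution Uniform(low, high)."""

    pop_labels: tuple[str, ...]
    drift_F: tuple[float, ...]
    n_haplotypes: tuple[int, ...]
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not (len(self.pop_labels) == len(self.drift_F) == len(self.n_haplotypes)):
            raise ValueError("pop_labels, drift_F and n_haplotypes must align")
        for F in self.drift_F:
            if not 0.0 < F < 1.0:
                raise ValueError(f"drift_F must be strictly in (0,1), got {F}")
        for n in self.n_haplotypes:
            if n < 2:
                raise ValueError("each population needs >= 2 haplotypes")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")


@dataclass(frozen=True)
class TractSpec:
    """A planted donor segment, 1-based inclusive bp coordinates."""

    chrom: str
    start_bp: int
    end_bp: int
    donor_pop: str
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("tract start_bp > end_bp")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0,1]")

    def overlaps(self, other: "TractSpec") -> bool:
        return (self.chrom == other.chrom
                and self.start_bp <= other.end_bp
                and other.start_bp <= self.end_bp)


@dataclass(frozen=True)
class SweepSpec:
    """Founder-copy sweep: a fraction ``carrier_fraction`` of haplotypes
    copy one founder outward from ``focal_bp`` for Exponential(mean
    ``mean_tract_bp``) distances on each side."""

    focal_bp: int
    carrier_fraction: float
    mean_tract_bp: float

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier_fraction must be in (0,1)")
        if self.mean_tract_bp <= 0:
            raise ValueError("mean_tract_bp must be > 0")


@dataclass
class TruthSet:
    """Ground truth emitted alongside every scenario."""

    tracts: list[tuple[str, int, TractSpec]] = field(default_factory=list)
    quartet_f_true: float | None = None
    sweep: SweepSpec | None = None

    def carrier_samples(self) -> list[str]:
        return sorted({s for s, _, _ in self.tracts})

    def tract_at(self, sample: str, hap: int, chrom: str, bp: float) -> TractSpec | None:
        for s, h, t in self.tracts:
            if (s, h) == (sample, hap) and t.chrom == chrom and t.start_bp <= bp <= t.end_bp:
                return t
        return None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "tracts": [
                {"sample": s, "hap": h, **dataclasses.asdict(t)}
                for s, h, t in self.tracts
            ],
            "quartet_f_true": self.quartet_f_true,
            "sweep": dataclasses.asdict(self.sweep) if self.sweep else None,
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        obj = json.loads(Path(path).read_text())
        tracts = [
            (d["sample"], d["hap"], TractSpec(
                chrom=d["chrom"], start_bp=d["start_bp"], end_bp=d["end_bp"],
                donor_pop=d["donor_pop"], carrier_fraction=d["carrier_fraction"]))
            for d in obj["tracts"]
        ]
        sweep = SweepSpec(**obj["sweep"]) if obj.get("sweep") else None
        return cls(tracts=tracts, quartet_f_true=obj.get("quartet_f_true"), sweep=sweep)


# ---------------------------------------------------------------------------
# Balding-Nichols machinery


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Population frequencies drifted from ancestral frequencies p.
    p is clipped away from {0,1} so nested draws stay well defined."""
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _haplotypes(rng: np.random.Generator, freq: np.ndarray, n: int) -> np.ndarray:
    return (rng.random((n, len(freq))) < freq).astype(np.int8)


def _site_frame(n_sites: int, bp_per_site: int, chrom: str) -> dict:
    pos = 1 + bp_per_site * np.arange(n_sites, dtype=np.int64)
    return {
        "chrom": np.full(n_sites, chrom, dtype=object),
        "pos": pos,
        "ref": np.full(n_sites, "A", dtype=object),
        "alt": np.full(n_sites, "T", dtype=object),
    }


def simulate_reference_panels(
    model: PopModel,
    n_sites: int,
    bp_per_site: int = DEFAULT_BP_PER_SITE,
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    """Draw one Balding-Nichols panel per population on a shared site
    frame.  Sites monomorphic across the union of panels are redrawn so
    every emitted site is biallelic.  Returns the stacked matrix and a
    frequency table (chrom, pos, ancestral, one column per population).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = model.ancestral_freq_range
    n_pops = len(model.pop_labels)

    p_anc = rng.uniform(lo, hi, size=n_sites)
    freqs = np.empty((n_pops, n_sites))
    haps = [np.empty((model.n_haplotypes[k], n_sites), dtype=np.int8)
            for k in range(n_pops)]

    todo = np.arange(n_sites)
    for _ in range(100):  # redraw monomorphic-union sites
        for k, F in enumerate(model.drift_F):
            freqs[k, todo] = _bn_draw(rng, p_anc[todo], F)
            haps[k][:, todo] = _haplotypes(rng, freqs[k, todo], model.n_haplotypes[k])
        stacked = np.vstack([h[:, todo] for h in haps])
        mono = (stacked.min(axis=0) == stacked.max(axis=0))
        if not mono.any():
            break
        todo = todo[mono]
        p_anc[todo] = rng.uniform(lo, hi, size=len(todo))
    frame = _site_frame(n_sites, bp_per_site, chrom)
    sample_ids = [f"{p}_{i:03d}" for k, p in enumerate(model.pop_labels)
                  for i in range(model.n_haplotypes[k] // 2)]
    for k, n in enumerate(model.n_haplotypes):
        if n % 2:
            raise ValueError("n_haplotypes must be even (2 per diploid sample)")
    matrix = HaplotypeMatrix(alleles=np.vstack(haps), sample_ids=sample_ids, **frame)
    freq_df = pd.DataFrame({"chrom": frame["chrom"], "pos": frame["pos"],
                            "ancestral": p_anc})
    for k, p in enumerate(model.pop_labels):
        freq_df[p] = freqs[k]
    return matrix, freq_df


def simulate_admixed_targets(
    ref_freqs: pd.DataFrame,
    background_pop: str,
    tracts: Sequence[TractSpec],
    n_targets: int,
    seed: int = 0,
    sample_prefix: str = "target",
) -> tuple[HaplotypeMatrix, TruthSet]:
    """Mosaic target genomes: background-pool frequency draws everywhere,
    donor-pool draws inside planted tracts on carrier samples.

    Carrier status is decided per diploid sample (both haplotypes carry
    the tract), matching the homozygous introgression blocks of a
    selfing crop; the truth set records each haplotype's tract.
    """
    for i, a in enumerate(tracts):
        for b in tracts[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"overlapping tracts: {a} / {b}")
        if a.donor_pop not in ref_freqs.columns:
            raise ValueError(f"unknown donor population {a.donor_pop!r}")
    if background_pop not in ref_freqs.columns:
        raise ValueError(f"unknown background population {background_pop!r}")

    rng = np.random.default_rng(seed)
    n_sites = len(ref_freqs)
    pos = ref_freqs["pos"].to_numpy()
    chrom = ref_freqs["chrom"].to_numpy()
    bg = ref_freqs[background_pop].to_numpy()

    alleles = np.empty((2 * n_targets, n_sites), dtype=np.int8)
    truth = TruthSet()
    sample_ids = [f"{sample_prefix}_{i:03d}" for i in range(n_targets)]
    for i, sid in enumerate(sample_ids):
        hap_pair = (rng.random((2, n_sites)) < bg).astype(np.int8)
        for t in tracts:
            if rng.random() < t.carrier_fraction:
                inside = (chrom == t.chrom) & (pos >= t.start_bp) & (pos <= t.end_bp)
                donor = ref_freqs[t.donor_pop].to_numpy()[inside]
                hap_pair[:, inside] = (rng.random((2, inside.sum())) < donor).astype(np.int8)
                truth.tracts.append((sid, 0, t))
                truth.tracts.append((sid, 1, t))
        alleles[2 * i:2 * i + 2] = hap_pair
    matrix = HaplotypeMatrix(
        alleles=alleles, sample_ids=sample_ids,
        chrom=chrom.astype(object), pos=pos,
        ref=ref_freqs.get("ref", pd.Series(["A"] * n_sites)).to_numpy(dtype=object),
        alt=ref_freqs.get("alt", pd.Series(["T"] * n_sites)).to_numpy(dtype=object),
    )
    return matrix, truth


def simulate_quartet(
    f_true: float,
    n_per_pop: int = 30,
    n_sites: int = 30_000,
    bp_per_site: int = DEFAULT_BP_PER_SITE,
    seed: int = 0,
    block_sites: int = 250,
    chrom: str = DEFAULT_CHROM,
) -> tuple[HaplotypeMatrix, TruthSet]:
    """Four-taxon gene-flow scenario.

    P1 and P2 are sister pools drifted from a shared internal lineage,
    P3 is a diverged donor pool, P4 a distant outgroup (F = 0.5).  A
    fraction ``f_true`` of sites — laid down in contiguous blocks of
    ``block_sites`` SNPs so jackknife blocks are non-trivial — has the
    P2 haplotypes drawn from the P3 population frequencies instead.
    """
    if not 0.0 <= f_true <= 1.0:
        raise ValueError("f_true must be in [0,1]")
    if n_per_pop < 2:
        raise ValueError("n_per_pop must be >= 2")
    rng = np.random.default_rng(seed)
    n_hap = n_per_pop if n_per_pop % 2 == 0 else n_per_pop + 1

    pops = ("P1", "P2", "P3", "P4")
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    intro = _block_mask(rng, n_sites, f_true, block_sites)
    freqs = {p: np.empty(n_sites) for p in pops}
    haps = {p: np.empty((n_hap, n_sites), dtype=np.int8) for p in pops}

    todo = np.arange(n_sites)
    for _ in range(100):  # redraw sites monomorphic across the union
        anc = p_anc[todo]
        lineage = _bn_draw(rng, anc, 0.2)            # internal P1/P2 ancestor
        freqs["P1"][todo] = _bn_draw(rng, lineage, 0.05)
        freqs["P2"][todo] = _bn_draw(rng, lineage, 0.05)
        freqs["P3"][todo] = _bn_draw(rng, anc, 0.2)
        freqs["P4"][todo] = _bn_draw(rng, anc, 0.5)
        p2_eff = np.where(intro[todo], freqs["P3"][todo], freqs["P2"][todo])
        haps["P1"][:, todo] = _haplotypes(rng, freqs["P1"][todo], n_hap)
        haps["P2"][:, todo] = _haplotypes(rng, p2_eff, n_hap)
        haps["P3"][:, todo] = _haplotypes(rng, freqs["P3"][todo], n_hap)
        haps["P4"][:, todo] = _haplotypes(rng, freqs["P4"][todo], n_hap)
        stacked = np.vstack([haps[p][:, todo] for p in pops])
        mono = (stacked.min(axis=0) == stacked.max(axis=0))
        if not mono.any():
            break
        todo = todo[mono]
        p_anc[todo] = rng.uniform(0.05, 0.95, size=len(todo))
    frame = _site_frame(n_sites, bp_per_site, chrom)
    sample_ids = [f"{p}_{i:03d}" for p in ("P1", "P2", "P3", "P4")
                  for i in range(n_hap // 2)]
    matrix = HaplotypeMatrix(
        alleles=np.vstack([haps[p] for p in ("P1", "P2", "P3", "P4")]),
        sample_ids=sample_ids, **frame)
    return matrix, TruthSet(quartet_f_true=f_true)


def _block_mask(rng: np.random.Generator, n_sites: int, f: float,
                block_sites: int) -> np.ndarray:
    """Contiguous-block site mask covering (approximately exactly) a
    fraction f of sites."""
    target = int(round(f * n_sites))
    mask = np.zeros(n_sites, dtype=bool)
    if target == 0:
        return mask
    n_segments = max(1, n_sites // block_sites)
    n_blocks = min(n_segments, int(np.ceil(target / block_sites)))
    chosen = rng.choice(n_segments, size=n_blocks, replace=False)
    remaining = target
    for seg in sorted(chosen):
        start = seg * block_sites
        length = min(block_sites, remaining, n_sites - start)
        mask[start:start + length] = True
        remaining -= length
        if remaining <= 0:
            break
    if remaining > 0:  # f close to 1: fill leftover sites
        free = np.flatnonzero(~mask)
        mask[free[:remaining]] = True
    return mask


def simulate_sweep_region(
    panel: HaplotypeMatrix,
    spec: SweepSpec,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, TruthSet]:
    """Overlay a founder-copy partial sweep on an existing panel.

    The site nearest ``focal_bp`` is the focal site (must be biallelic
    in the panel).  A fraction q of haplotypes become carriers: they
    take the ALT allele at the focal site and copy the founder's
    alleles outward for Exponential(mean_tract_bp) bp on each side;
    non-carriers take REF at the focal site so the swept-allele
    frequency is q up to rounding.
    """
    focal = int(np.argmin(np.abs(panel.pos - spec.focal_bp)))
    col = panel.alleles[:, focal]
    called = col[col != -1]
    if called.min() == called.max():
        raise ValueError("focal site is monomorphic in the panel")
    n = panel.n_haplotypes
    n_carriers = int(round(spec.carrier_fraction * n))
    truth = TruthSet(sweep=spec)
    if n_carriers == 0:
        return panel, truth
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    carriers = rng.choice(n, size=n_carriers, replace=False)
    alt_rows = np.flatnonzero(col == 1)
    founder = int(rng.choice(alt_rows))
    founder_row = panel.alleles[founder].copy()
    alleles[:, focal] = 0
    for h in carriers:
        left = spec.focal_bp - rng.exponential(spec.mean_tract_bp)
        right = spec.focal_bp + rng.exponential(spec.mean_tract_bp)
        span = (panel.pos >= left) & (panel.pos <= right)
        alleles[h, span] = founder_row[span]
        alleles[h, focal] = 1
    out = HaplotypeMatrix(alleles=alleles, sample_ids=list(panel.sample_ids),
                          chrom=panel.chrom, pos=panel.pos,
                          ref=panel.ref, alt=panel.alt)
    return out, truth


# ---------------------------------------------------------------------------
# Emission


def emit_dataset(
    matrix: HaplotypeMatrix,
    samples: SampleTable,
    truth: TruthSet,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the scenario to disk: phased VCF, population TSV, truth
    tracts BED4 (0-based half-open) and truth JSON."""
    missing = set(samples.df["sample"]) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"sample table names absent from matrix: {sorted(missing)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "data.vcf",
        "samples": outdir / "samples.tsv",
        "truth_bed": outdir / "truth_tracts.bed",
        "truth_json": outdir / "truth.json",
    }
    write_vcf(matrix, paths["vcf"], seed=seed)
    write_sample_table(samples, paths["samples"])
    with open(paths["truth_bed"], "w") as fh:
        for s, h, t in truth.tracts:
            fh.write(f"{t.chrom}\t{t.start_bp - 1}\t{t.end_bp}\t{s}|{h}|{t.donor_pop}\n")
    truth.to_json(paths["truth_json"])
    return paths


# ---------------------------------------------------------------------------
# Canonical study scenarios


def painting_scenario(
    seed: int = 0,
    n_sites: int = 30_000,
    bp_per_site: int = DEFAULT_BP_PER_SITE,
    n_ref_haplotypes: int = 60,
    n_targets: int = 20,
    drift_F: float = 0.3,
    tract: TractSpec | None = None,
) -> tuple[HaplotypeMatrix, SampleTable, TruthSet]:
    """Three diverged reference pools plus admixed targets carrying one
    planted 3.8 Mb donor tract on a 30 Mb pseudo-chromosome (default
    geometry: 1 SNP/kb, Balding-Nichols F = 0.3, 60 haplotypes per
    reference pool, 20 targets, carrier fraction 0.5)."""
    model = PopModel(
        pop_labels=("japonica", "indica", "aus"),
        drift_F=(drift_F,) * 3,
        n_haplotypes=(n_ref_haplotypes,) * 3,
    )
    panel, freqs = simulate_reference_panels(model, n_sites, bp_per_site, seed=seed)
    if tract is None:
        tract = TractSpec(chrom=DEFAULT_CHROM, start_bp=17_900_000,
                          end_bp=21_700_000, donor_pop="aus", carrier_fraction=0.5)
    targets, truth = simulate_admixed_targets(
        freqs, "japonica", [tract], n_targets, seed=seed + 1)
    matrix = _merge(panel, targets)
    records = [(s, s.rsplit("_", 1)[0], "reference") for s in panel.sample_ids]
    records += [(s, "japonica", "target") for s in targets.sample_ids]
    return matrix, SampleTable.from_records(records), truth


def quartet_scenario(
    f_true: float,
    seed: int = 0,
    n_per_pop: int = 30,
    n_sites: int = 30_000,
) -> tuple[HaplotypeMatrix, SampleTable, TruthSet]:
    """Default four-taxon scenario: 30 Mb at 1 SNP/kb, 30 haplotypes per
    population, gene flow P3 -> P2 in contiguous blocks."""
    matrix, truth = simulate_quartet(f_true, n_per_pop=n_per_pop,
                                     n_sites=n_sites, seed=seed)
    roles = {"P1": "reference", "P2": "target", "P3": "reference", "P4": "outgroup"}
    records = [(s, s.rsplit("_", 1)[0], roles[s.rsplit("_", 1)[0]])
               for s in matrix.sample_ids]
    return matrix, SampleTable.from_records(records), truth


def sweep_scenario(
    seed: int = 0,
    with_sweep: bool = True,
    n_haplotypes: int = 200,
    carrier_fraction: float = 0.5,
    mean_tract_bp: float = 150_000.0,
    region_bp: int = 5_000_000,
    dense_span_bp: int = 500_000,
    dense_n_snps: int = 1_000,
    drift_F: float = 0.1,
) -> tuple[HaplotypeMatrix, SampleTable, TruthSet]:
    """One population on a 5 Mb pseudo-chromosome: neutral background at
    1 SNP/kb with a denser 500 kb / 1,000 SNP central region; optionally
    a founder-copy sweep (q = 0.5, mean tract 150 kb) at the region
    centre."""
    rng = np.random.default_rng(seed)
    centre = region_bp // 2
    dense_lo = centre - dense_span_bp // 2
    dense_hi = centre + dense_span_bp // 2
    sparse = np.arange(1, region_bp + 1, 1_000, dtype=np.int64)
    sparse = sparse[(sparse < dense_lo) | (sparse > dense_hi)]
    dense = np.linspace(dense_lo, dense_hi, dense_n_snps).astype(np.int64)
    pos = np.unique(np.concatenate([sparse, dense]))
    n_sites = len(pos)

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    freq = _bn_draw(rng, p_anc, drift_F)
    alleles = _haplotypes(rng, freq, n_haplotypes)
    # redraw sites monomorphic in the sample
    for _ in range(100):
        mono = alleles.min(axis=0) == alleles.max(axis=0)
        if not mono.any():
            break
        p_anc[mono] = rng.uniform(0.05, 0.95, size=mono.sum())
        freq[mono] = _bn_draw(rng, p_anc[mono], drift_F)
        alleles[:, mono] = _haplotypes(rng, freq[mono], n_haplotypes)
    sample_ids = [f"pop_{i:03d}" for i in range(n_haplotypes // 2)]
    matrix = HaplotypeMatrix(
        alleles=alleles, sample_ids=sample_ids,
        chrom=np.full(n_sites, DEFAULT_CHROM, dtype=object), pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object))
    truth = TruthSet()
    if with_sweep:
        spec = SweepSpec(focal_bp=centre, carrier_fraction=carrier_fraction,
                         mean_tract_bp=mean_tract_bp)
        matrix, truth = simulate_sweep_region(matrix, spec, seed=seed + 1)
    table = SampleTable.from_records([(s, "pop", "target") for s in sample_ids])
    return matrix, table, truth


def _merge(*matrices: HaplotypeMatrix) -> HaplotypeMatrix:
    from .genio import merge_haplotypes

    return merge_haplotypes(list(matrices))
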