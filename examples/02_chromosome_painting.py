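"""Paint admixed genomes against three reference pools and score the
painting against the generator's truth.

Each 150-SNP half-overlapping window is reduced by PCA; a kernel
density per reference pool on the first five components gives each
target haplotype a posterior over ancestries.  Labels with posterior
>= 0.8 colour the window; runs of equal labels merge into tracts.
"""

from introkit import painting, simulate as sim

tract = sim.TractSpec(chrom="chr1", start_bp=1_000_000, end_bp=1_300_000,
                      donor_pop="aus", carrier_fraction=0.5)
matrix, table, truth = sim.painting_scenario(
    seed=2, n_sites=3_000, n_ref_haplotypes=30, n_targets=6, tract=tract)

tracks = painting.paint_genome(matrix, table)
report = painting.evaluate_painting(tracks, truth, background_pop="japonica")

print(f"per-slice label accuracy: {report.accuracy:.4f} "
      f"over {report.n_slices} slices")
carrier, hap, spec = truth.tracts[0]
track = next(t for t in tracks if (t.sample, t.hap) == (carrier, hap))
aus = [t for t in track.tracts if t[3] == "aus"]
print(f"truth tract on {carrier}/hap{hap}: "
      f"[{spec.start_bp:,}, {spec.end_bp:,}] from '{spec.donor_pop}'")
print(f"painted aus tract(s) on that haplotype: "
      f"{[(a, b) for _, a, b, _ in aus]}")
print("A boundary error below one window step (75 SNPs ~ 75 kb here)")
print("means the painted tract edges sit within one slice of the truth.")
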