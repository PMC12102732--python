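"""Generate a synthetic multipass peptide-mapping dataset.

Builds a random 300-residue target protein, plants true peptides with a
bimodal ion-mobility peak-width (FWHM) population plus rule-violating
decoys, and emits per-trendline, per-replicate peptide-ID tables in the
folder layout the pipeline consumes.
"""

from pathlib import Path

from cimmerge import default_simulation, write_simulation

gt, model, plan, tables = default_simulation(seed=1)
out = Path("scratch/simulated")
write_simulation(tables, gt, out)

print(f"protein: {gt.protein.protein_id}, {gt.protein.length} residues")
print(f"planted: {len(gt.true_peptides)} true peptides, "
      f"{len(gt.false_positives)} decoys (one per filter rule)")
for tag, reps in tables.items():
    sizes = [len(t) for t in reps]
    print(f"  {tag}: {len(reps)} replicates with {sizes} rows")
print(f"written under {out}/ (per-tag subfolders + ground_truth.csv)")
# Row counts differ across trendline folders because each trendline only
# detects peptides whose true peak width its smoothing line matches; the
# single-pass folder (1_1) sees the unwrapped population at a lower ceiling.
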