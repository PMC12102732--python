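# cimmerge

Merging, filtering and trendline optimization for **multipass cyclic
ion-mobility (cIM) HDMS<sup>E</sup> peptide mapping**, the peptide-identification
step that precedes hydrogen/deuterium-exchange mass spectrometry (HDX-MS).

## The problem

Bottom-up HDX-MS lives or dies on the peptide map: the more unique peptides
identified for a target protein, the higher the sequence coverage (fraction
of residues seen by ≥ 1 peptide) and redundancy (mean number of peptides per
covered residue), and hence the better the spatial resolution of deuterium-uptake
measurements. Cyclic ion-mobility instruments boost identifications by letting
ions make multiple passes around the mobility cell — but in multipass mode
fast ions lap slow ones inside the fixed 200-bin drift-time (DT) window
("wrap-around"), destroying the linear relationship between DT and
ion-mobility peak width (FWHM) that peak-detection software assumes when it
chooses its kernel-smoothing width.

The workaround is to process the same multipass dataset iteratively under
several candidate **DT-vs-FWHM trendlines** — straight lines defined by the
assumed FWHM at DT bin 0 and bin 200, written `11-13` for
(FWHM<sub>start</sub> = 11, FWHM<sub>end</sub> = 13) — and then merge and
filter the resulting peptide-ID lists. Each trendline smooths a different
slice of the wrapped width distribution correctly, so each detects a partly
unique peptide population. `cimmerge` automates this data reduction:

* **per-trendline pipeline** — merge replicate peptide-ID lists on the
  identity key (protein, sequence, modification); filter on replicate count
  and retention-time relative standard deviation (RT-RSD, %); average the
  remaining metrics across replicates and filter on them (products per amino
  acid, intensity, length window, matched/consecutive products, summed
  product intensity, PLGS score, |ppm| mass error); rank by PLGS score and
  keep the top record per key;
* **best-trendline selection** — run the pipeline per trendline folder and
  report unique-peptide counts;
* **multi-sequence merging** — pool complementary single-pass
  (auto-calculated trendline, folder `1_1`) and multipass (best trendline)
  experiments;
* **multi-trendline merging** — pool *every* trendline's output; the final
  unique-key set is exactly the union of the per-trendline filtered sets;
* **coverage/redundancy reporting** and curation accounting;
* a **simulator** that stands in for the proprietary peak-detection engine:
  planted true peptides with trendline-dependent Gaussian-kernel detection
  (`p = p_max · exp(−(FWHM_trendline(dt) − FWHM_true)² / 2σ²)`), wrap-around
  DT arithmetic, and per-rule false positives, so the whole pipeline can be
  validated with known ground truth (precision/recall).

## Worked example

```python
from cimmerge import (FilterThresholds, default_simulation, merge_multitrendline,
                      detected_true_keys, score_against_truth, coverage_report)
from cimmerge.filter_pipeline import run_tag_pipeline

gt, model, plan, tables = default_simulation(seed=1)   # 300-residue protein,
th = FilterThresholds()                                # 3 replicates, trendlines 7-9 & 19-21

for tag in sorted(tables):
    print(tag, len(run_tag_pipeline(tables[tag], th)))
final = merge_multitrendline(tables, th)
print("pooled:", len(final))
print(score_against_truth(final, gt, detected_true_keys(tables, gt)))
print(coverage_report(final, gt.protein).summary())
```

prints

```
19_21 65
1_1 116
7_9 76
pooled: 145
(1.0, 0.9666666666666667)
SIMPROT: 145 peptides, 98.7% coverage, redundancy 7.23
```

The two multipass trendlines each recover one component of the bimodal
width population (65 and 76 unique peptides), the single pass sees the
unwrapped population (116), and pooling all three folders yields 145 unique
peptides — more than any single route — at precision 1.0 (all planted
false positives are removed by the threshold filters) and recall 0.97 of
the detectable true peptides, covering 98.7% of the protein with an average
depth of 7.2 peptides per covered residue.

The `examples/` directory holds one short script per capability
(simulation, best-trendline selection, multi-trendline pooling, curation
accounting); each prints what it computes and what the numbers mean.

## Command line

```bash
cimmerge process --trendlines "7-9,19-21" --out scratch/processed --seed 1
cimmerge best-trendline --input scratch/processed
cimmerge merge-filter --input scratch/processed --mode multi-trendline
cimmerge coverage --peptides final_peptides_<stamp>.csv --fasta target.fasta
```

`process` runs the pluggable backend (the simulator by default) once per
trendline, sorting outputs into per-trendline subfolders (`11_13`, …;
single-pass is always `1_1`), and writes a batch-plan text file listing the
equivalent vendor-engine invocations. Filter thresholds live in a flat YAML
profile (`--thresholds`); field names mirror `FilterThresholds`.

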