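# citegate

Flow-cytometry-style gating of CITE-seq surface-protein (ADT) data, purity
scoring against ground-truth cell labels, data-driven selection of
additional gating markers, and non-linear gate refinement.

## Who this is for

Immunologists and computational biologists who sort cell populations by
surface-marker gating (FACS or its *in silico* CITE-seq analogue) and want
to know — and improve — how pure those populations really are. Given a
cells × markers ADT matrix and per-cell ground-truth labels (e.g.
multi-omics annotations), `citegate`:

1. applies hierarchical flow-style gates (1-D thresholds and 2-D polygons)
   with density-driven cut-offs;
2. cross-tabulates gate membership against the truth labels and reports
   accuracy, sensitivity, specificity and purity per gate, plus Jaccard /
   Jensen–Shannon overlap between competing gate definitions;
3. ranks candidate extra markers by how well they separate true positives
   from contaminants, combining a differential-expression filter
   (|log2FC| ≥ 2, BH-adjusted Wilcoxon p ≤ 0.05), a per-marker sigmoid-kernel
   SVM (cross-validated precision/recall/F1), and the unbiased squared
   maximum mean discrepancy

       MMD²_u = Σ_{i≠j}k(x_i,x_j)/(m(m−1)) + Σ_{i≠j}k(y_i,y_j)/(n(n−1)) − 2Σ_{i,j}k(x_i,y_j)/(mn);

4. refines a gate to the highest-density region (HDR) of its true-positive
   cells over the selected marker pair — a non-linear polygon gate enclosing
   a fraction α of the TP density — and reports the purity gain, TP yield
   and per-contaminant removal;
5. tests whether within-gate composition differs across sample groups
   (one-way ANOVA + pairwise Wilcoxon with Holm correction, with an
   eligibility rule requiring > 3 non-zero individuals per group).

A fully seeded synthetic-data generator (negative-binomial ADT counts,
Dirichlet per-sample compositions, plantable marker effects) makes every
stage testable without any external download. See `docs/methods.md` for
the model details and design decisions.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from citegate.simulate import default_scenarios, simulate_dataset
from citegate.workflow import run_classical_gating, run_selection, run_refinement
from citegate.purity import confusion_table, purity_metrics

# a dataset whose naive gate is contaminated by an IgD+ CD27- memory-like
# population, separable on CD21/CD20/CD24
cfg = default_scenarios(seed=7)["contaminated-naive"]
ds = simulate_dataset(cfg)

run = run_classical_gating(ds)            # CLR -> thresholds -> panel
tab = confusion_table(run.assignment, ds.truth_label)
m = purity_metrics(tab, "naive", "naive")
print(f"naive gate: {m.tp + m.fp} cells, purity {m.purity:.3f}, "
      f"sensitivity {m.sensitivity:.3f}, specificity {m.specificity:.3f}")

sel = run_selection(run, "naive", seed=7) # DE filter + SVM + MMD ranking
print("selected markers:", sel.selected)

refined, report = run_refinement(run, "naive", sel)   # HDR polygon gate
print(f"purity {report.purity_before:.3f} -> {report.purity_after:.3f} "
      f"(+{report.purity_increase_points:.1f} points), TP yield {report.tp_yield:.3f}")
```

prints

```
naive gate: 2713 cells, purity 0.709, sensitivity 1.000, specificity 0.726
selected markers: ['CD21', 'CD11c']
purity 0.709 -> 0.999 (+29.1 points), TP yield 0.929
```

Reading: the classical IgD/CD27 quadrant gate captures 2713 cells of which
only 70.9% truly are naïve B cells; the selection pipeline identifies CD21
(the contaminant is CD21-low) as the most discriminating extra marker; and
restricting the gate to the 90% highest-density region of the true naïve
cells in CD21 × CD11c space removes essentially all contaminants while
retaining 92.9% of the true cells.

The same pipeline is available from the shell:

```bash
citegate simulate --preset contaminated-naive --seed 7 -o out/sim
citegate gate    --matrix out/sim/matrix.csv --metadata out/sim/metadata.tsv -o out/gated
citegate purity  --assignments out/gated/assignments.tsv --metadata out/sim/metadata.tsv -o out/purity
citegate select  --matrix out/sim/matrix.csv --metadata out/sim/metadata.tsv --gate naive --seed 7 -o out/sel
citegate refine  --matrix out/sim/matrix.csv --metadata out/sim/metadata.tsv --gate naive --seed 7 -o out/ref
```

Each subcommand writes TSV outputs plus a `manifest.json` recording inputs,
parameters, seed and version; identical commands with identical seeds give
byte-identical outputs.

## Input formats

- ADT matrix: Matrix Market triplets (`matrix.mtx` with `features.tsv` /
  `barcodes.tsv` sidecars, orientation auto-detected) or dense CSV/TSV with
  cells as rows and a header of marker names.
- Metadata: TSV with a `cell_id` column and any of `truth_label`,
  `sample_id`, `group`. Cells absent from the metadata are kept with
  missing labels; purity computations exclude them and report the count.
- Gates and panels: YAML/JSON configs with `gt`/`lt`/`between`/`polygon`
  atoms; thresholds may be literals or `auto(quantile=0.995, reference=<gate>)`.

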