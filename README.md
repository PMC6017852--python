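# qamskit

Single-marker quantitation toolkit for HPLC-UV multi-component assays.

QAMS (quantitative analysis of multi-components by single marker) quantifies
several analytes against one reference standard through pre-established
relative correction factors (RCFs), instead of running one calibration curve
per analyte (the external standard method, ESM). `qamskit` implements the
full workflow for a six-alkaloid assay (analytes `PQ-1` … `PQ-6`, with
`PQ-6` as the single marker) end to end:

- **`qamskit.synthetic`** — chromatogram simulator with known ground truth:
  (exponentially modified) Gaussian peaks placed by a relative-retention-time
  library, areas following per-analyte linear detector responses, Gaussian
  baseline noise, optional drift; mixed-standard dilution series; 20-batch
  sample sets; blanks. Fully deterministic under a seed.
- **`qamskit.peaks`** — robust baseline estimation, SNR-thresholded peak
  detection, trapezoidal integration with valley/baseline-return bounds, and
  system-suitability metrics (theoretical plates `5.54·(t/w½)²`, USP tailing
  factor, resolution), plus RRT-window analyte assignment with relative peak
  areas.
- **`qamskit.calibration`** — unweighted OLS calibration (`area = a·conc + b`),
  ESM quantitation with out-of-range flagging, and S/N-based LOD (S/N=3) /
  LOQ (S/N=10).
- **`qamskit.qams`** — RCF estimation `f = (A_s/C_s)/(A_x/C_x)` per level,
  mean/RSD aggregation, robustness-grid summaries, single-marker sample
  quantitation `C_x = f_x·(C_s/A_s)·A_x`, and paired-t ESM-vs-QAMS method
  comparison.
- **`qamskit.validation`** — stability / precision / repeatability /
  reproducibility replicate RSDs of RRT and RPA, and standard-addition
  recovery.
- **`qamskit.chemometrics`** — column standardization, in-repo Ward
  hierarchical clustering (Lance–Williams recurrence, `ward.d2` and `ward.d`
  variants) with Newick export, correlation-matrix PCA with a fixed sign
  convention, and radar-plot group tables.
- **`qamskit.io` / `qamskit.cli`** — CSV interchange formats and packaged
  reference tables (`calibration`, `rcf_levels`, `robustness`,
  `batch_contents`) at full published precision.

## CLI

```sh
qamskit simulate  --seed 7 --out out/sim           # 20 batches + blank, CSV traces
qamskit peaks     out/sim/S1_r0.csv --out out/pk   # peak tables
qamskit calibrate --seed 7 --out out/cal --noiseless
qamskit rcf       --seed 7 --out out/rcf           # per-level RCFs + summary
qamskit quantify  --seed 7 --out out/q --rcf-table out/rcf/rcf_levels.csv
qamskit chemometrics --out out/chem                # HCA labels, Newick, PCA, radar
qamskit validate  --seed 7 --out out/val           # replicate RSD designs
qamskit reproduce --out out/rep                    # recompute packaged summaries,
                                                   # report pass/fail
```

Every stochastic stage requires `--seed`; omission is an error, never a
silent default.

A note on clustering preprocessing: correlation-matrix PCA standardizes
implicitly, but for Ward HCA the packaged 20-batch table reproduces its
published three-group partition only from the *raw* content matrix —
z-scoring moves the two boundary samples across groups under every Ward
variant. The reproduction path therefore clusters raw contents by default;
pass `--standardize` (CLI) or `standardize()` (API) to cluster z-scores.

## Known input-data quirks (documented, not patched)

- The published per-level RCF table's mean row prints 0.974 for `PQ-5`,
  but its own column averages 0.9795; recomputed values are used.
- The published batch RSD row prints 24.9 % for `PQ-2`; both content
  columns give 25.0 % after rounding.
- The published working-solution ranges differ slightly from the published
  linear ranges (e.g. `PQ-1` 11.0–41.3 vs 10.9–40.9 µg/mL); the standard
  series uses the former, calibration fixtures the latter.
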