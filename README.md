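# nirchem

Vis/NIR chemometrics pipeline for non-destructive fruit-composition
prediction (total soluble solids and the BrimA taste index):

- **spectra** — wide-CSV spectral I/O, scan averaging, reflectance →
  absorbance (A = log10(1/R));
- **preprocess** — SNV/MSC scatter correction and wavelet-shrinkage
  smoothing (self-contained periodized orthogonal DWT; haar, db2, db4,
  sym4, sym8);
- **chemistry** — NaOH titration formula for titratable acidity and
  BrimA = TSS − K·TA (K = 5 by default);
- **neuralnet** — MLP with the MATLAB-style transfer catalog (logsig,
  tansig, purelin, radbas, satlins, hardlim, tribas, netinv) and trainers
  `traingd` (batch gradient descent), `traincgb` (conjugate gradient with
  Powell–Beale restarts), `trains` (random-order incremental updates);
- **sa_select** — simulated-annealing search over fixed-size wavelength
  subsets, scored by the validation MSE of a small MLP (memoized,
  deterministic per seed);
- **ica** — imperialist competitive algorithm over the mixed
  integer/categorical space of the five MLP structure parameters (layers,
  neurons, transfers, train method, learn method);
- **plsr** — single-response NIPALS partial least squares regression with
  seeded cross-validated component selection;
- **evaluate** — repeated random 60/10/30 train/validation/test splits with
  R, R², MSE, RMSE, MAE per iteration, plus mean ± SD / quartile /
  best-iteration summaries and box-plot statistics;
- **synthetic** — seeded generator of benchmark spectra + chemistry with
  known ground truth (Gaussian absorption bands near 950–990 nm, latent
  confounding absorbers, scatter, noise), so the whole pipeline is testable
  without any external data.

## CLI

Each stage is a subcommand writing its artifacts plus a manifest into an
output directory:

```bash
nirchem simulate   --out runs/data --seed 1
nirchem preprocess --spectra runs/data/spectra.csv --out runs/pre
nirchem select     --spectra runs/pre/preprocessed.csv \
                   --chemistry runs/data/chemistry.csv \
                   --property tss --out runs/sel --seed 1
nirchem tune       --spectra runs/pre/preprocessed.csv \
                   --chemistry runs/data/chemistry.csv \
                   --selection runs/sel/selection_tss.json \
                   --property tss --out runs/tune --seed 1
nirchem evaluate   --spectra runs/pre/preprocessed.csv \
                   --chemistry runs/data/chemistry.csv \
                   --selection runs/sel/selection_tss.json \
                   --ann-config runs/tune/ann_config_tss.json \
                   --property tss --method ann-ica --n-iter 500 \
                   --out runs/eval
nirchem evaluate   --spectra runs/pre/preprocessed.csv \
                   --chemistry runs/data/chemistry.csv \
                   --selection runs/sel/selection_tss.json \
                   --property tss --method plsr --n-iter 500 \
                   --out runs/eval
nirchem report     --summaries runs/eval/summary_ann-ica_tss.csv \
                   --summaries runs/eval/summary_plsr_tss.csv \
                   --out runs/comparison.csv
```

`nirchem train` fits and saves a single final model (`--method ann-ica` or
`--method plsr`).

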