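# lfbmil

Weakly supervised deep-learning-style analysis of Luxol-fast-blue (LFB)
stained brain histology: slide-level classification of cognitive impairment
from noisy antemortem labels, attention-based localization of the evidence
to white matter, and positive-pixel quantification of myelin staining in
the tiles the model attends to most.

## Who this is for and what it does

Neuropathology cohorts often have gigapixel whole-slide images and only
*donor-level*, noisy cognitive labels (CDR, MMSE, clinical diagnosis) — no
pixel annotations. Attention-based multiple instance learning (MIL) fits
this setting: a slide is a bag of tiles, each tile k yields a feature
vector h_k, a gated attention network scores it,

    e_k = w^T ( tanh(V h_k) ⊙ sigmoid(U h_k) ),    a = softmax(e),

and the slide representation z = Σ_k a_k h_k feeds a classifier that
predicts P(cognitively impaired). The attention weights a_k then act as an
interpretability signal: z-transformed per slide, summarized per annotated
region (grey vs white matter) and compared with paired t-tests; the top-100
attention tiles are quantified by counting pixels in a dark-blue HSI hue
band (LFB stains CNS myelin dark blue, so fewer dark-blue pixels means
myelin pallor), with the dark/light-blue count ratio as a per-slide
normalization against staining-intensity variation. Downstream statistics
relate the model's probability estimates and stain medians to pathoclinical
traits: Spearman correlations, permutation-calibrated differential
correlation (Fisher z), and conditional-independence G-tests
(G = 2N·MI on discretized variables).

Since the matching human cohort is not openly deposited, the package ships
a first-class synthetic data module: cohorts whose impairment depends on
age, noisy/missing cognitive measures, and rendered slides with grey/white
matter compartments, nucleus dots, per-slide stain gain, and a planted
reduction of white-matter dark-blue density in impaired donors. Every
analysis step is tested for recovery of that planted structure and for
calibration under the null.

## Worked example

The numbered drivers under `analysis/` run the demo profile (120 donors,
one 1024×1024 px slide each, planted 30% white-matter staining reduction,
10% label noise, tenfold Monte Carlo cross-validation):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_train_mil.py
python analysis/03_interpret_attention.py
python analysis/04_quantify_stain.py
python analysis/05_associate_traits.py
```

(the `lfbmil` console script runs the same stages from a YAML config:
`lfbmil all --config my_run.yaml`). The drivers print, in order:

```
fold AUCs: [0.829, 0.829, 0.514, 0.943, 0.743, 0.8, 1.0, 0.771, 0.943, 0.743]
mean AUC = 0.811, Wilcoxon vs 0.5: p = 0.0059
mean balanced accuracy = 0.813
median WM attention z = +0.79; median GM attention z = -0.87
predicted CI vs NCI, median_dark: 2269.2 vs 3326.4, Welch t = -16.03, p = 4.10e-31
```

Reading these: the classifier separates noisily labelled impaired from
unimpaired donors well above chance in every fold but one (the Wilcoxon
signed-rank test aggregates the ten folds against AUC 0.5); the best-fold
model's attention concentrates on white matter rather than grey matter;
and the slides the model *predicts* to be impaired have markedly fewer
dark-blue (myelin-like) pixels in their top-attention tiles — i.e. the
model found the planted myelin-pallor signal and the stain quantification
recovers it. The association stage further shows the predicted probability
rising with age (ρ ≈ 0.37) and the top-tile dark count falling with it
(ρ ≈ −0.27), with conditional-independence tests separating the
label–staining association from age.

## Layout

- `src/lfbmil/` — the library: `simulate` (synthetic cohorts and slides),
  `labels` (CI/NCI labelling), `tiling` (segmentation, tiling, features),
  `mil` (attention-MIL model, training, Monte Carlo cross-validation),
  `interpret` (z-scores, heatmaps, region statistics, top tiles), `stain`
  (HSI conversion, positive pixel counting, group tests, 2-D KDE),
  `stats` (rank/differential correlation, G-tests), `pipeline` + `cli`
  (staged, resumable orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model assumptions, parameter choices, and known
  limitations.
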