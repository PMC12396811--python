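# branchdyn

Branch-resolved analysis of single-cell expression dynamics along a
developmental trajectory: how a gene's mRNA distribution, its transcriptional
burst kinetics, and its interactions with other genes change **before a cell
fate branch point, at the branch point, and on each post-branch lineage**.

Single-cell RNA-seq snapshots ordered in pseudotime make these questions
answerable without time-course data: every "pseudotime point" is really a
window of cells, and each window carries a full mRNA count distribution that
mechanistic models can be fitted to. `branchdyn` is aimed at computational
biologists who already have a count matrix plus a trajectory annotation
(pseudotime, stage cluster, branch label per cell) from tools such as
trajectory-inference or RNA-velocity pipelines, and want the downstream,
branch-resolved statistics.

## The models

**Windowed distributions.** Cells of each branch segment
(`pre → branch_point → {branch1, branch2}`) are sorted by pseudotime and cut
into equal-frequency windows (optionally overlapping for smooth trend
series); each window yields an empirical count distribution P(m).

**Gamma mixtures by KL minimization.** The stationary mRNA law of the
two-state (telegraph) gene — promoter switching OFF→ON at rate k_on, ON→OFF
at k_off, transcribing at k_syn, mRNA degrading at rate δ = 1 — is, in the
bursty regime, a Gamma distribution with shape α = k_on and rate β̃ = k_off/k_syn
(mean α/β̃). Unimodal windows are fitted with one Gamma, bimodal/trimodal
windows with convex combinations of two or three Gammas,

&nbsp;&nbsp;&nbsp;&nbsp;p(x) = Σᵢ ωᵢ · β̃ᵢ^αᵢ / Γ(αᵢ) · x^(αᵢ−1) e^(−β̃ᵢ x),&nbsp;&nbsp;Σᵢ ωᵢ = 1,

by minimizing the Kullback–Leibler divergence KL(P_data ‖ P_model) with the
continuous density discretized over [m−½, m+½) at each observed integer m.
Modality (m = 1, 2, 3) is selected by BIC with ties going to the simpler
model. Per-component moments are closed-form: mean = loc + α/β̃, variance =
α/β̃², skewness = 2/√α, excess kurtosis = 6/α.

**Burst kinetics.** Counts follow the Beta-Poisson law X ~ Poisson(s·k_syn·p),
p ~ Beta(k_on, k_off), with s the per-cell size factor (total counts over the
median total). The pmf is evaluated by Gauss–Jacobi quadrature, whose weight
function absorbs the Beta density exactly, and (k_on, k_off, k_syn) are
fitted by multi-start maximum likelihood. Burst size **BS = k_syn/k_off**
(mRNAs per ON episode) and burst frequency **BF = k_on** (episodes per mRNA
lifetime) are tracked window-by-window and labelled
increasing/decreasing/constant by Spearman correlation with window order.

**Markers and interactions.** A marker gene must rank in the top 30 by
mean-binned standardized dispersion (HVG criterion) *and* shift its
distribution significantly across the branch (two-sample Kolmogorov–Smirnov,
Benjamini–Hochberg FDR 0.05). Gene-pair structure is quantified by
kernel joint densities, per-window random-forest regulation strengths
(GENIE3-style normalized importances), and 1-Wasserstein distances between
expression distributions across stages or branches.

**Synthetic branching data.** A first-class generator produces count matrices
and annotations from stage-dependent two-state kinetics (or explicit Gamma
mixtures for trimodal stages), with log-normal cell sizes — the ground truth
every statistical claim in the test suite is validated against.

## Worked example

`examples/02_fit_modality.py` simulates a gene programmed bimodal before the
branch, unimodal at the branch point, bimodal on branch1 and trimodal on
branch2, then fits each segment:

```
pre: n=800 cells, selected m=2 (KL=0.0105)
  weight=0.470 shape=   52.49 rate= 5.224 -> mean= 10.05 var=  1.92 skew=0.276
  weight=0.530 shape=   97.20 rate= 3.206 -> mean= 30.32 var=  9.46 skew=0.203
  mixture peaks at [9.86, 30.01]

branch_point: n=200 cells, selected m=1 (KL=0.0391)
  weight=1.000 shape=   19.69 rate= 1.155 -> mean= 17.05 var= 14.77 skew=0.451
  mixture peaks at [16.19]
...
branch2: n=200 cells, selected m=3 (KL=0.0267)
  ...
  mixture peaks at [10.0, 19.68, 30.37]
```

The selected modalities (2 / 1 / 2 / 3) match the programmed laws, and the
fitted mixture peaks recover the programmed component modes near 10, 20 and
30 mRNAs. `examples/03_burst_kinetics.py` prints the per-window BS/BF table
for a gene with burst size ramped 12→6 before the branch, 6→14 on branch1 and
6→3 on branch2, ending with

```
burst-size trend per segment (label, Spearman rho):
  pre      decreasing   rho=-0.96
  branch1  increasing   rho=+0.99
  branch2  decreasing   rho=-0.88
```

— the opposite post-branch trends that distinguish the two lineages. The
other examples cover the generator itself, the marker screen (the five
programmed markers are flagged with q ≈ 10⁻⁶, background genes are not) and
the gene-pair analyses.

A thin CLI mirrors the library: `branchdyn simulate|windows|fit-dist|bursts|
markers|interactions|run-all` (see `branchdyn --help`); `run-all` chains the
pipeline and writes a checksummed report bundle.

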