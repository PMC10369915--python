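# sh2screen

Quantitative analysis of SH2-domain phosphopeptide specificity and its
functional consequences, built around the biochemistry of SHP2 — a
tyrosine phosphatase whose N-terminal SH2 (phosphotyrosine-recognition)
domain both recruits the enzyme to phosphoproteins and allosterically
activates it. Disease-associated point mutations in the SH2
ligand-binding pockets (e.g. the Noonan-syndrome mutation T42A) can
change not just binding affinity but binding *specificity*, biasing
which upstream signals activate the enzyme. This package implements the
full quantitative pipeline needed to characterize such mutants:

- **Screen scoring** — count deep-sequencing reads from bacterial
  peptide-display selections against a defined phosphopeptide library
  and compute per-peptide enrichment scores,
  `score_i = f_i(selected) / f_i(input)`, with pseudocount smoothing
  and replicate averaging.
- **Hit calling and logos** — calibrate a score cutoff from
  tyrosine-free negative-control peptides (which cannot be
  phosphorylated and so sample the non-specific background), call
  enriched sets, compute set overlaps, and build position-specific
  log2-odds logos of hit versus library amino-acid composition aligned
  on the phosphotyrosine, plus saturation-mutagenesis
  (log2 variant/wild-type) matrices.
- **Binding** — exact fluorescence-polarization models: the
  ligand-depletion quadratic for direct titrations,
  `bound = ((R+L+K_D) − √((R+L+K_D)² − 4RL))/2`, and the exact ternary
  competitive equilibrium (cubic in free receptor — no IC50 or
  Cheng–Prusoff approximation) for competition titrations; bounded
  multi-start least-squares fits with standard errors; geometric-mean
  K_D fold-changes with Welch inference on log K_D.
- **Activation** — EC50 fits of phosphopeptide-stimulated phosphatase
  activation, `rate(c) = basal + (max−basal)·c/(EC50+c)`, log–log
  Pearson correlation of EC50 against N-SH2 K_D, and basal
  catalytic-efficiency (k_cat/K_M) fold-changes.
- **Energetics** — double-mutant-cycle thermodynamics:
  `ΔΔG = RT·ln(K_D,state/K_D,wt)` and the interaction energy
  `ΔΔG_int = ΔΔG_AB − ΔΔG_A − ΔΔG_B`, used to ask whether two residues
  (e.g. Thr42 and Lys55) are energetically coupled.
- **Synthetic data** — a generator for screens (multinomial sampling
  after one multiplicative selection round), titrations, and activation
  curves with known ground truth, so every stage is testable end to end
  with no external data.

## Worked example

```python
import numpy as np
from sh2screen import *

# 1) synthetic specificity screen with a known position-weight truth
lib = make_fixture_library(n_sites=400, n_controls=40, peptide_length=9, seed=7)
prefs = {(-2, "V"): 8.0, (1, "A"): 8.0, (2, "E"): 6.0, (-1, "W"): 0.125}
weights = weights_from_position_preferences(lib, prefs)
truth = ScreenTruth(weights, depth_input=300_000, depth_selected=300_000, seed=8)
ct_in, ct_sel = simulate_screen(lib, truth)
et = enrichment_scores(frequencies(ct_in, 1), frequencies(ct_sel, 1),
                       domain_label="N-SH2 synthetic")
cutoff = calibrate_cutoff(et, lib, max_control_fraction=0.02)
hits = call_hits(et, lib, cutoff)
logo = logo_matrix(hits, lib, pseudocount=1.0, window=(-4, 4))

# 2) competition FP titration and Ki fit
truth = TitrationTruth("competition", {"ki": 5.0, "probe_kd": 0.5,
    "receptor_total": 1.0, "probe_total": 0.01,
    "signal_free": 60.0, "signal_bound": 210.0}, noise_sd=2.0, seed=3)
ds = simulate_titration(truth, np.concatenate([[0.0], np.logspace(-2, 3.5, 11)]))
fit = fit_competition(ds)

# 3) double-mutant cycle from reported affinity fold-changes
ddg = ddg_from_fold(90)                     # T42A alone, MILR1 peptide
coupling = coupling_from_folds(90, 28)      # T42A in WT vs K55R background
```

Printing the key quantities from those objects gives:

```
calibrated cutoff: 0.48
hits: 78 of 440 peptides (control FPR 0.000)
logo value at (-2, V): +2.05
logo value at (-1, W): -2.54
fitted Ki: 4.43 +/- 0.54 uM
T42A ddG (MILR1, 90-fold): -2.67 kcal/mol
T42A/K55R coupling (MILR1, 90 vs 28): +0.69 kcal/mol
T42A/K55R coupling (Gab2, 20 vs 43): -0.45 kcal/mol
```

Reading the numbers: the control-calibrated cutoff (0.48) leaves no
tyrosine-free control above threshold; the logo recovers the planted
specificity (+2.05 for the favored −2 Val, −2.54 for the disfavored
−1 Trp, both in log2 units); the competition fit recovers the true
K_i = 5 µM within ~1 standard error; a 90-fold affinity gain is
−2.67 kcal/mol of binding free energy; and the T42A effect on MILR1 is
attenuated by K55R (+0.69 kcal/mol, sub-additive coupling) but enhanced
on Gab2 (−0.45 kcal/mol, super-additive) — the signature of an
energetic link between the two positions.

A `sh2screen` console script exposes the same stages as subcommands
(`simulate`, `count`, `score`, `call-hits`, `logo`, `scan`, `fit-fp`,
`fit-activation`, `cycle`, `run`); `sh2screen run --config config.yaml`
executes the whole screen pipeline and writes a manifest so reruns are
byte-identical.

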