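# qpicd — single-cell death dynamics from quantitative phase imaging

Quantitative phase imaging (QPI) records, per pixel, the optical phase
delay of light passing through a cell — proportional to the dry-mass
surface density times thickness — without any exogenous label.  `qpicd`
turns time-lapse QPI movies into a quantitative description of how single
cells die, for cell biologists and drug-response researchers who need to
distinguish **apoptosis** (programmed death: shrinkage, rounding, a
sharpened nuclear boundary) from **necrosis** (accidental death: swelling,
loss of intracellular mass density) and from unperturbed cells, and to
characterize *when* and *how fast* each morphological change happens.

## The method

1. **Features.** Eleven features per cell per frame: cell area,
   circularity (4πA/P²), eccentricity (minor/major axis), solidity,
   optical volume Σ Δφ·(λ/2π)·ΔxΔy (∝ dry mass), phase SD, and —
   after splitting the cell at 1.1× the within-cell Otsu threshold into a
   bright central region C and its periphery P — the mean central phase,
   mean peripheral phase, their ratio, the fried-egg score area(C)/area,
   and a nuclear-edge score (mean |∇Δφ| over a two-pixel elliptical band
   detected at the nuclear boundary, 0 when no qualifying ellipse exists).

2. **Dynamics.** Each feature's time course, normalized within sliding
   13-point windows, is fitted by a logistic transition

       f(t) = Amplitude / (1 + exp(Gain·(Cutoff − t)))

   where Amplitude is the signed total change, Gain the rate (h⁻¹) and
   Cutoff the transition time.  The per-cell transition time T is the
   cutoff at which most features reach R² ≥ 0.7; each feature's final fit
   maximizes |Amplitude × Gain| over cutoffs in [T, T + 2 h].

3. **Classification.** Per-cell Amplitude, Gain and Amplitude×Gain values
   are screened by Wilcoxon rank-sum tests; selected parameters feed an
   RBF-kernel SVM evaluated over 500 stratified 2:1:2
   train/validation/test splits (min–max scaling + gamma correction fitted
   on the training split only), plus a Fisher LDA projection for
   visualization.

Because no public QPI movies of dying cells exist, the package ships a
first-class synthetic generator: elliptical two-level phase phantoms whose
geometry and phase follow class-specific logistic trajectories (necrosis:
slow swelling and central-phase collapse; apoptosis: fast rounding and a
nuclear-edge ring), with seeded phase noise and homeostatic fluctuations.
Every stage is tested against this exact ground truth; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
import pandas as pd
from qpicd import CohortConfig, simulate_cohort, analyze_stack, fit_cell

cells, truth = simulate_cohort(n_normal=1, n_apoptotic=1, n_necrotic=1, seed=42)
for cell in cells:
    features = analyze_stack(cell.stack, cell.cell_id)   # segment+track+extract
    record = fit_cell(features)                          # sigmoid fits + vote
    edge = record.fits["nuclear_edge_score"]
    print(
        f"{cell.spec.class_label:>10}: T={record.transition_time} h, "
        f"{record.n_sigmoidal} sigmoidal features, "
        f"area amplitude {record.fits['cell_area'].amplitude:+.3f}, "
        f"central-phase amplitude {record.fits['mean_central_phase'].amplitude:+.3f}, "
        f"nuclear-edge A*G {edge.amplitude * edge.gain:+.2f}"
    )
```

prints

```
    normal: T=None h, 0 sigmoidal features, area amplitude +0.000, central-phase amplitude +0.000, nuclear-edge A*G +0.00
 apoptotic: T=1.3 h, 6 sigmoidal features, area amplitude +0.014, central-phase amplitude +0.008, nuclear-edge A*G +1.81
  necrotic: T=1.9 h, 9 sigmoidal features, area amplitude +0.078, central-phase amplitude -0.154, nuclear-edge A*G -1.39
```

The normal cell never transitions (no feature fits a sigmoid, so it is
flagged and recorded with zero amplitudes).  The apoptotic cell transitions
at T = 1.3 h with 6 of 11 features sigmoidal: its area barely changes, and
the strongly positive nuclear-edge Amplitude×Gain reports the sharp nuclear
ring appearing.  The necrotic cell swells (+7.8 % fitted area amplitude),
its central phase drops (−15.4 %, loss of central dry mass) and its
nuclear-edge score *falls* as the intracellular contrast fades — the sign
pattern the classifier exploits.

The same pipeline runs from the shell:

```bash
qpicd all --seed 0 --out runs/demo          # simulate → … → classify
qpicd simulate --out cohort/                # or stage by stage
qpicd segment cohort/cell_0000.tif --out labels.tif
```

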