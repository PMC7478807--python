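# nfkbinfo

How much information about *which* ligand stimulated a cell survives the trip
from receptor, through nuclear NFκB dynamics, into the expression of a target
gene?  `nfkbinfo` is a simulation-and-analysis toolkit for that question.  It
is aimed at systems biologists studying dynamic signal encoding who want to
quantify, in bits, the fidelity of information transmission from stimulus
identity through single-cell signaling trajectories into gene expression — and
to ask which gene-expression parameters limit that fidelity.

## What it computes

The pipeline has four stages:

1. **Encoding (surrogate).**  Single-cell nuclear-NFκB trajectories over
   1–480 min for five innate-immune ligands (TNF, LPS, PolyIC, CpG, Pam3CSK),
   each with its characteristic waveform — damped oscillations, sustained
   plateau, delayed slow rise, fast transient.  Cell-to-cell (extrinsic)
   variability enters by log-normal sampling of the waveform parameters at a
   common coefficient of variation (CV).  Trajectories simulated with an
   external mechanistic model can be plugged in from a long-format CSV
   instead.

2. **Gene expression.**  A single non-dimensionalized ODE driven by the
   normalized NFκB input x(t):

       dG/dt = k0 + ks · x(t−τ)ⁿ / (kbⁿ + x(t−τ)ⁿ) − kd · G,   G(0) = k0/kd

   with basal rate k0, NFκB-driven rate ks, degradation rate kd,
   half-saturation kb, Hill coefficient n, and transcriptional delay τ
   (minutes).  The same log-normal noise model supplies per-cell parameters.

3. **Information.**  Each trajectory is read at d time points (default
   [50, 100, 150, 300, 450] min) and treated as a point in ℝᵈ.  Differential
   entropies are estimated without binning by the Kozachenko–Leonenko
   k-nearest-neighbor estimator (k = 10), and mutual information between
   ligand identity L and response R follows MI(R;L) = H(R) − Σᵢ qᵢ H(R|L=lᵢ)
   with equiprobable ligands, reported in bits.  MI is bounded by
   log₂(5) ≈ 2.32 bits for five ligands.

4. **Optimization.**  Simulated annealing maximizes MI over the six gene
   parameters: one uniformly chosen parameter moves per iteration by
   ±(5% × u) of its value, Metropolis acceptance with geometric cooling,
   termination when ΔMI < 10⁻² bits holds over a window of accepted
   iterations, repeated from independent uniform starting guesses.

Experiment orchestrations reproduce the standard analyses: MI as a function
of extrinsic-noise CV per stage, MI distributions over sampled gene
parameters, nominal-vs-optimized parameter attribution, single-parameter
variability sweeps, expression-variability and ligand-specificity metrics.

## Worked example

```python
import numpy as np
from nfkbinfo import (
    StimulusPanel, generate_ensemble, normalize_ensemble,
    simulate_expression_ensemble, nominal_params,
    embed_timepoints, mutual_information,
)

panel = StimulusPanel()                       # TNF, LPS, PolyIC, CpG, Pam3CSK
nfkb = normalize_ensemble(generate_ensemble(panel, 1000, cv=0.25, rng=42))
est = mutual_information(embed_timepoints(nfkb))
print(f"encoding MI:       {est.mi_bits:.3f} bits  (ceiling log2(5) = {np.log2(5):.3f})")

gene = simulate_expression_ensemble(nfkb, nominal_params(), noisy=False)
print(f"gene MI (no noise): {mutual_information(embed_timepoints(gene)).mi_bits:.3f} bits")

noisy = simulate_expression_ensemble(nfkb, nominal_params(), cv=0.25, noisy=True, rng=43)
print(f"gene MI (CV 25%):   {mutual_information(embed_timepoints(noisy)).mi_bits:.3f} bits")
```

prints

```
encoding MI:       2.210 bits  (ceiling log2(5) = 2.322)
gene MI (no noise): 1.837 bits
gene MI (CV 25%):   1.111 bits
```

Reading: at 25% cell-to-cell variability the five ligands are still nearly
perfectly distinguishable from NFκB dynamics alone (2.21 of 2.32 bits).  A
noise-free gene converts most of that into distinguishable expression
patterns (1.84 bits); adding biochemical noise to the gene stage costs a
further ~0.7 bits — a loss that parameter optimization (see the `optimize`
subcommand) can partly recover.

## Command line

Every stage is also a subcommand of the `nfkbinfo` console script, reading an
optional JSON/YAML run-config and writing a results directory with a config
copy, CSV/JSON outputs, and a manifest of content hashes (identical config +
seed ⇒ byte-identical outputs):

```bash
nfkbinfo simulate -o runs/sim --seed 1          # trajectories.csv (5×1000 cells)
nfkbinfo mi --trajectories runs/sim/trajectories.csv --normalize -o runs/mi
nfkbinfo optimize -o runs/opt --seed 1          # SA traces + summary
```

Subcommands: `simulate`, `express`, `mi`, `converge`, `bias`, `sweep`,
`optimize`, `combos`, `specificity`.

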