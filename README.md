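# cagrna

Quantitative analysis of CAG-repeat RNA hairpin stability, mobility, and
ATP interactions in the cellular environment — the measurement pipeline
behind in-cell temperature-jump FRET melting experiments, FRAP mobility
assays, nuclear-speckle colocalization imaging, and MD-trajectory
hydrogen-bond analysis. A seeded synthetic-data module generates every
input with planted ground truth, so the full pipeline is testable on a
laptop without raw microscopy or trajectory data.

It is aimed at researchers analyzing in-cell folding stability of labeled
RNA (or similar two-state folders) who need the fitting machinery rather
than the microscope control.

## The model

A CAG-repeat hairpin is treated as a two-state folder, F ⇌ U. Around the
melting temperature *T*<sub>m</sub> the standard free energy of unfolding
is linearized with the first-order cooperativity parameter *g*⁽¹⁾
(kJ·mol⁻¹·K⁻¹, negative for heat-induced unfolding):

```
ΔG_u(T) = g⁽¹⁾ · (T − T_m),          ΔG_u^θ,37°C = (310 K − T_m) · g⁽¹⁾
K_u(T)  = exp(−ΔG_u / RT),           f_u = K_u / (1 + K_u)
```

Because in-cell melting curves lack resolved baselines, (*T*<sub>m</sub>,
*g*⁽¹⁾) are extracted kinetically: a ladder of consecutive temperature
jumps (19 × 25 s) is applied, each jump's donor/acceptor relaxation is fit
with a single exponential, and the slow-phase amplitudes are fit with the
finite-difference two-state model

```
a_k = c · [f_u(T_k) − f_u(T_{k−1})] + m · (T_k − T_{k−1})
```

where *c* is a signal scale and *m* absorbs linear dye/baseline drift.
Sample temperature per jump is calibrated from the exponentially
temperature-dependent fluorescence of a Rhodamine B reference.

Around this core the package provides: FRAP mobile fractions
(*f*<sub>mobile</sub> from a single-exponential recovery fit), object-based
RNA/speckle colocalization and speckle/nucleoplasm partition coefficients,
ATP–RNA hydrogen-bond counting on trajectories (donor–acceptor distance
< 0.4 nm, donor–hydrogen–acceptor angle > 120°, bucketed by base / ribose /
phosphate moiety), glycosidic χ torsions, RMSD to the iteratively refined
average structure, and one-way ANOVA with post-hoc Tukey (–Kramer)
comparisons plus Gaussian error propagation of ΔG₃₇.

## Worked example

```python
import numpy as np
from cagrna.thermo import MeltingParameters, unfolded_fraction
from cagrna.tjump import JumpProtocol, build_amplitude_curve, fit_melting, fit_relaxation
from cagrna.synthetic import NoiseSpec, gen_tjump_experiment

# simulate a 19-jump ladder at the in vitro buffer parameters
params = MeltingParameters(tm=349.0, g1=-20.7 / 39.0)
protocol = JumpProtocol(target_temperatures=tuple(np.linspace(303, 358, 19)),
                        start_temperature=300.0)
exp = gen_tjump_experiment(params, protocol, NoiseSpec(sigma=0.0, seed=1))

# refit the melting parameters from the traces
fits = [fit_relaxation(t) for t in exp.traces]
result = fit_melting(build_amplitude_curve(fits, protocol))
print(f"T_m = {result.params.tm:.1f} K, dG37 = {result.dg37:.2f} kJ/mol")
print(f"unfolded at 37C: {100 * unfolded_fraction(6.8, 310.0):.1f} %")
```

prints

```
T_m = 349.0 K, dG37 = 20.70 kJ/mol
unfolded at 37C: 6.7 %
```

i.e. the pipeline returns the generating stability exactly on noiseless
data, and a hairpin destabilized to 6.8 kJ/mol is still ~93% folded at
37 °C — stability is lost in the cell, structure largely is not.

## Analysis drivers

`analysis/01…06` run the full narrative on synthetic data: simulate all
inputs (`01`), fit melting parameters per environment (`02`), FRAP mobile
fractions per construct with group statistics (`03`), colocalization and
partition coefficient (`04`), native-vs-unwound ATP contact analysis
(`05`), and the ΔG₃₇ group comparison (`06`). Tables land in `results/`,
regenerable raw data in `scratch/`.

A thin CLI mirrors the stages: `cagrna fit-melt`, `fit-frap`, `coloc`,
`md-contacts`, `simulate`, `report`.

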