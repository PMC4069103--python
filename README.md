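# phstab

Analysis toolkit for studying **pH-dependent stability of Ntn-hydrolases**
(penicillin acylase and relatives): per-domain trajectory statistics, a
DTW-based trajectory-comparison statistic, geometric hydrogen-bond network
analysis, near-to-attack-conformation (NAC) scoring, pKa-threshold
protonation assignment, subfamily-specific position (SSP) ranking in labeled
alignments, and enzyme inactivation / Michaelis–Menten kinetics fitting —
with seeded synthetic-data generators for every input class, so every
statistic can be validated against planted ground truth.

The toolkit is aimed at protein engineers and computational enzymologists
who compare MD simulations of an enzyme under different conditions (e.g.
neutral vs alkaline pH, wild type vs point mutant) and want a quantitative,
reproducible answer to "which structural domain is destabilized, by how
much, and is the designed mutant actually more stable?"

## The statistics at the core

**Trajectory comparison (Δ<sub>RMSD</sub>, f).** For two MD runs of the
same system, the per-frame backbone RMSD series (2000 frames each) are
smoothed with a 10-frame moving average and aligned by dynamic time warping
under a Sakoe–Chiba band |i−j| ≤ w (w = 500 frames for reporting; 0 means
no warping). Over the aligned pairs:

- Δ<sub>RMSD</sub> = ⟨RMSD<sub>MD2</sub> − RMSD<sub>MD1</sub>⟩ — the signed
  degree of (de)stabilization, in Å;
- f = fraction of aligned pairs with RMSD<sub>MD1</sub> ≥ RMSD<sub>MD2</sub>
  — the overlap of the two curves; f ≲ 0.05 flags a significant difference.

Replicate sets (3 runs per model) are cross-compared over all 3 × 3 ordered
pairs and summarised as mean ± sample SD.

**H-bonds and NAC.** A hydrogen bond is accepted at donor–acceptor distance
≤ 3.5 Å and D–H–A angle in 145–180°; per-residue-pair persistence is the
fraction of frames with a qualifying bond. The productive substrate pose
requires three active-site distances (Ser Oγ–carbonyl C; carbonyl O to the
two oxyanion-hole amide nitrogens) all ≤ 3.5 Å.

**SSPs.** Alignment columns conserved within each functional subfamily but
different between subfamilies are scored by corrected mutual information
I(residue; subfamily) in bits with a seeded permutation test, after a
0.25 bits/column template-similarity filter and >95%-identity redundancy
removal.

**Kinetics.** First-order inactivation A(t) = A₀·e<sup>−k_in·t</sup> and
Michaelis–Menten v = k_cat·E₀·[S]/(K_M + [S]) by nonlinear least squares;
stabilization fold = k_in(reference)/k_in(variant).

## Worked example

Fitting synthetic kinetic data generated at the constants reported for
wild-type penicillin acylase and its stabilized Dβ484N variant (2% noise):

```python
import numpy as np
from phstab import (KineticsSynthConfig, gen_decay, gen_mm,
                    fit_inactivation, fit_michaelis_menten,
                    catalytic_efficiency, stabilization_fold)

wt = fit_michaelis_menten(gen_mm(KineticsSynthConfig(k_cat=25.0, k_m=25.0, noise_sigma=0.02, seed=1)))
mut = fit_michaelis_menten(gen_mm(KineticsSynthConfig(k_cat=19.5, k_m=14.8, noise_sigma=0.02, seed=2)))
print(f"WT:    k_cat/K_M = {catalytic_efficiency(wt):.2g} uM^-1 s^-1")
print(f"D484N: k_cat/K_M = {catalytic_efficiency(mut):.2g} uM^-1 s^-1")

def decay(k, seed):
    times = tuple(np.linspace(0, 1.5 / k, 21))
    return fit_inactivation(gen_decay(KineticsSynthConfig(k_in=k, times=times, noise_sigma=0.02, seed=seed)))

kw, km = decay(0.0026, 3), decay(0.00029, 4)
print(f"k_in(WT) = {kw.k_in:.5f} min^-1, k_in(D484N) = {km.k_in:.6f} min^-1")
print(f"stabilization fold = {stabilization_fold(kw.k_in, km.k_in):.1f}")
```

prints

```
WT:    k_cat/K_M = 1 uM^-1 s^-1
D484N: k_cat/K_M = 1.3 uM^-1 s^-1
k_in(WT) = 0.00260 min^-1, k_in(D484N) = 0.000291 min^-1
stabilization fold = 9.0
```

i.e. the fits recover the generating efficiencies (1.0 and 1.3 µM⁻¹s⁻¹)
and the ~9-fold stabilization of the variant at alkaline pH.

The two-model trajectory experiment works the same way: generate replicate
runs with a planted drifting domain, compute per-domain RMSD series, and
cross-compare:

```python
from phstab import gen_replicate_models, rmsd_series, compare_models, TSCompareConfig
m1, m2, part = gen_replicate_models(seed=0)
series = lambda model, dom: [rmsd_series(t, part.selection(dom), part.selection("core")) for t in model]
r = compare_models(series(m1, "B1"), series(m2, "B1"), TSCompareConfig())
print(r.delta_rmsd, r.f)   # positive delta, f ~ 0 -> significant destabilization
```

## Command line

`phstab --config config.yaml <stage>` with stages `prepare` (protonation
decisions), `stability`, `hbond`, `nac`, `ssp`, `kinetics`, `synth`, and
`report`; see the docstring of `phstab.cli` for the configuration layout.
All outputs are deterministic CSV keyed by the configured seed.

## Layout

- `src/phstab/` — the library (`structio`, `protonate`, `hbond`, `nac`,
  `tscmp`, `ssp`, `kinetics`, `synth`, `cli`)
- `tests/` — pytest suite, including property tests and independent oracles
- `docs/methods.md` — models, parameter choices, numerical details and
  limitations
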