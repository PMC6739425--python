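# rnaloops

Integrative structure analysis for long non-coding RNAs: chemical-probing
reactivity processing, probing-directed secondary-structure inference,
in vivo / ex vivo differential protection calling, kissing-loop pseudoknot
discovery with compensatory-mutant design, alignment-based conservation and
covariation scoring, and single-particle AFM / Mg²⁺-titration compaction
analytics.

## The problem

Large structured RNAs such as the tumor-suppressor lncRNA MEG3 fold into
multi-domain architectures in which distal motifs can interact through
long-range base pairing. A hairpin terminal loop carrying a short motif
(e.g. GUGAG) can pair with complementary tandem repeats (TRs) hundreds of
nucleotides away, forming alternative, mutually exclusive pseudoknots
("kissing loops") that drive global compaction and are required for
function. Establishing such an interaction combines several quantitative
strands of evidence:

* **Chemical probing** (SHAPE with 1M7/1M6/NMIA, DMS, hydroxyl-radical
  footprinting) gives per-nucleotide reactivities *S&#x2071;*. Reactivities are
  box-plot normalized (outliers above Q3 + 1.5·IQR removed, capped at 10% of
  the data; the factor is the mean of the top decile of survivors) and
  classified — SHAPE: 0–0.40 not reactive, 0.40–0.85 moderately reactive,
  > 0.85 very reactive; HRF: four solvent-protection classes at
  0.29 / 0.58 / 0.86.
* **Probing-directed folding** adds a pseudo-energy
  ΔG(i) = *m*·ln(*S*&#x2071; + 1) + *b* (defaults *m* = 2.6, *b* = −0.8 kcal/mol)
  per paired nucleotide to a nearest-neighbour model, minimized by a
  Zuker-style dynamic program; a McCaskill partition function yields pair
  probabilities p(i,j) and per-nucleotide Shannon entropies
  S(i) = −Σ p·log₁₀p.
* **Differential probing** (deltaSHAPE-style) compares ex vivo and in vivo
  profiles through smoothed differences Δᵢ, a Z-factor
  1 − 1.96·(σ_ex + σ_in)/|Δᵢ| and a standard score, flagging
  protein-protected sites.
* **Pseudoknot scanning** enumerates antiparallel Watson–Crick/wobble
  complements between hairpin-loop windows and distal single-stranded
  windows, labels repeats TR1…TRn in 5′→3′ order, groups registers competing
  for the same loop nucleotides, and designs compensatory double mutants
  (e.g. a loop G→C rescued by the paired repeat U→G) whose functional rescue
  evidences the pairing in vivo.
* **Biophysics**: row-wise AFM power spectral densities with auto-affine
  fits PSD(f) = a₀·f^(−γ); the intersection of the low- and high-frequency
  fits marks a characteristic frequency f\*, and L = 1/f\* tracks particle
  size, so compaction is 100·(L₀ − L₁)/L₀. Mg²⁺ titrations of the hydration
  radius are fitted with the Hill isotherm
  R_h(c) = R_∞ + (R₀ − R_∞)/(1 + (c/C_half)ⁿ) whose midpoint is C_Mg1/2.

Every input class can be generated synthetically (seeded) so the entire
pipeline is testable without any experimental download.

## Worked example

```python
from rnaloops import (gen_core, scan_kissing, design_all_compensatory,
                      simulate_titration, fit_hill)

seq, structure, _ = gen_core(seed=1)          # 320-nt core, 6 planted TRs
registers = scan_kissing(seq, structure)
print(f"{len(registers)} registers")
for r in registers[:3]:
    print(r.label, r.loop_interval, r.repeat_interval)

loop_g = registers[0].loop_interval[0] + 2    # a G of the GUGAG loop motif
designs = design_all_compensatory(registers, (loop_g, seq[loop_g-1], "C"), seq)
print([d.name for d in designs])

fit = fit_hill(simulate_titration(12.0, 9.6, 1.0, 2.0, noise_sd=0.1, seed=1))
print(fit.summary())
```

prints

```
6 registers
TR1 (44, 48) (170, 174)
TR2 (44, 48) (175, 179)
TR3 (44, 48) (180, 184)
['G46C/C172G', 'G46C/C177G', 'G46C/C182G', 'G46C/C187G', 'G46C/C192G', 'G46C/C197G']
Hill titration fit
------------------
R_h,0        :   12.014 nm  (se 0.034)
R_h,inf      :    9.643 nm  (se 0.034)
C_Mg1/2      :   0.9795 mM  (se 0.0508)
Hill n       :    2.167     (se 0.206)
compaction   :    19.73 %
direction    : compaction
midpoint in data range: True
residual sd  : 0.0683 nm
```

The scanner finds exactly the six planted tandem-repeat registers, all
competing for the same loop (one mutual-exclusivity group); one loop point
mutation yields six compensatory double-mutant designs, one per register;
and the titration fit recovers the planted folding midpoint (1.0 mM) and the
20% compaction between the extended (12 nm) and compact (9.6 nm) states.

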