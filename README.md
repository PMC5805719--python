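# sarcokit

Quantitative tooling for thin-filament regulation and sarcomere
contractility experiments.

Striated-muscle contraction is gated by the thin filament: tropomyosin (Tm)
sits in a *blocked* position on actin, moves to a *closed* position when
Ca²⁺ binds troponin, and is pushed further open when myosin heads bind.
The N-terminal region of myosin binding protein-C (MyBP-C) also shifts Tm
from blocked to closed, and the three isoforms (slow-skeletal,
fast-skeletal, cardiac) do so to different degrees, while some of them also
drag on filament sliding at saturating Ca²⁺.  `sarcokit` packages the
quantitative machinery that such experiments need:

* **`thin_filament`** — a stochastic Markov model of a chain of regulatory
  units, each blocked (B), closed (C) or myosin-bound (M):

  `B → C` at `a = k_on·ca^n/(ca^n + ca50^n) + θ·k_act`, `C → B` at `k_off`,
  `C → M` at `f_app`, `M → C` at `g_app`,

  where `θ` is MyBP-C fragment occupancy and nearest-neighbour coupling
  `γ` multiplies a unit's B→C rate (and divides its C→B rate) per active
  neighbour.  The force proxy is the fraction of units in M.  Protocols:
  steady-state force–pCa curves, release–restretch tension redevelopment
  (k_tr), and unloaded sarcomere-shortening twitches driven by a calcium
  transient.
* **`fiber`** — permeabilized-fiber analysis: four-parameter Hill fits of
  force–pCa (`F = floor + (ceiling−floor)/(1 + 10^{n_H(pCa−pCa₅₀)})`),
  single-exponential k_tr fits, NADH-coupled ATPase rates calibrated by
  ADP injections, linear tension-cost fits, and the 80%-of-maximal-tension
  integrity filter.
* **`motility`** — in vitro motility statistics: per-filament velocities,
  mobile-fraction classification, the statistic *mean velocity × fraction
  moving ± SEM*, and sigmoidal dose–response fits versus pCa.
* **`myocyte`** — sarcomere-length twitch kinetics of paced myocytes: beat
  averaging, time to 10/50/90% baseline recovery, relaxation constant τ
  from a log-linear fit, and the Western-blot replacement-level formula
  `myc/(myc + endogenous)`.
* **`calcium`** — free Ca²⁺ and pCa of EGTA-buffered activating/relaxing
  solutions and their volumetric mixing series (1:1 Ca:EGTA binding with a
  single apparent K_d).
* **`synthetic`** — seeded generators for every input above, each with a
  declared ground truth, so the full pipeline is testable end to end.

## Worked example

```python
import sarcokit as sk
from sarcokit.motility import downsample, motility_statistic
from sarcokit.synthetic import gen_tracks

# pCa of the standard equimolar Ca-EGTA activating solution
sol = sk.SolutionSpec(total_ca=0.02, total_egta=0.02)
print("pCa of activating solution: %.2f" % sk.pca_of(sk.free_calcium(sol)))

# fit a noisy synthetic force-pCa dataset
ds, truth = sk.gen_force_pca(pca50=5.8, n_h=2.0, noise_sd=0.02, seed=1)
fit = sk.fit_hill(ds)
print("force-pCa fit: pCa50 = %.3f, n_H = %.2f" % (fit.pca50, fit.n_h))

# cardiac-fragment inhibition of filament sliding at saturating calcium
for label, iso, conc in [("control", "none", 0.0),
                         ("C0C2 0.25 uM", "cardiac", 0.25e-6)]:
    tracks, _ = gen_tracks(4.0, 300, seed=1 if iso == "none" else 501,
                           effect=iso, frag_conc=conc)
    st = motility_statistic([downsample(t, 2.0) for t in tracks])
    print("%-13s velocity x fraction = %.2f um/s" % (label, st.product))
```

prints

```
pCa of activating solution: 4.50
force-pCa fit: pCa50 = 5.796, n_H = 1.89
control       velocity x fraction = 4.31 um/s
C0C2 0.25 uM  velocity x fraction = 2.39 um/s
```

The Hill fit recovers the generating pCa₅₀ of 5.8 to within the declared
noise, and the cardiac N-terminal fragment at its 0.25 µM working
concentration reduces the motility statistic by ~43%, the encoded
high-calcium drag effect.

A command-line surface mirrors the library
(`sarcokit buffer|sim|fiber|motility|myocyte|synth ...`), e.g.
`sarcokit buffer pca --total-ca-mm 20 --total-egta-mm 20` prints `4.50`.

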