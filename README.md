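# symport

Analysis toolkit for two questions about Na⁺-coupled sugar transporters
(SGLTs) and, more generally, Na⁺-binding proteins:

1. **What does a good protein Na⁺ coordination site look like?**
   Tools to read crystal structures, detect the coordination shell around
   each Na⁺ ion, classify every donor contact (side-chain O/N, main-chain
   carbonyl, water), flag bidentate carboxylates and Ser/Thr pairs at
   consecutive sequence positions, aggregate corpus-level census statistics,
   and search a census for sites geometrically similar to a query — e.g. a
   site built from a bidentate Asp plus adjacent Thr/Ser hydroxyls, the
   composition proposed for the accessory "Na3" site of hSGLT1.
2. **What do voltage-clamp measurements say about transporter function?**
   Fits for the standard oocyte protocols: Hill activation for apparent
   affinities, inhibition dose–response with competitive K_i correction,
   Boltzmann Q–V analysis of pre-steady-state charge, K_i from Q_max
   suppression, and Na⁺-to-sugar coupling stoichiometry from reversal
   potentials.

The package is aimed at structural biologists and transporter
physiologists who want these analyses as small, tested, scriptable pieces.
Because no lab data or bulk PDB download ships with it, a synthetic-data
layer generates idealized coordination-site structures (valid PDB/mmCIF
files) and simulated electrophysiology tables from the same models the
fitting code assumes, so the entire pipeline is exercisable offline.

## Models

* Hill activation: `I(S) = I_max · Sⁿ / (K_0.5ⁿ + Sⁿ)`; `K_0.5` is the
  apparent affinity, `n_H` a lower bound on binding-site multiplicity.
* Inhibition: `I(i) = I_0 / (1 + i/IC50)` with the competitive correction
  `K_i = IC50 / (1 + S/K_0.5)` (so `K_i = IC50/2` when the assay runs at
  `S = K_0.5`).
* Charge movement: `Q(V) = Q_off + Q_max / (1 + exp(zF(V − V_0.5)/RT))`,
  and `Q_max(i) = Q_max,0 / (1 + i/K_i)` for inhibitor lock-in.
* Stoichiometry: at the reversal potential the cycle free energy vanishes,
  giving `V_rev = (RT/F)[ln(Na_o/Na_i) + (1/n)·ln(S_o/S_i)]` for n Na⁺ per
  neutral sugar; `n` is read off as `(RT/F)` divided by the slope of
  `V_rev` against `ln S_o`.

## Worked example

```python
import numpy as np
from symport import *

# simulate a wild-type sugar dose-response (K_0.5 = 0.9 mM, n_H = 1.61),
# 8 concentrations x 5 replicates, 5% multiplicative noise, then refit
tbl = simulate_measurements(EphysSimSpec(
    "hill_activation", {"i_max": 1.0, "k_half": 0.9, "n_h": 1.61},
    np.geomspace(0.05, 50, 8), replicates=5, noise_sigma=0.05, seed=0))
fit = fit_hill_activation(tbl)
print(f"K_0.5 = {fit.k_half:.3f} +/- {fit.k_half_se:.3f} mM")
# K_0.5 = 0.937 +/- 0.036 mM   (generating value 0.9 mM)

# coupling stoichiometry from simulated reversal potentials (n = 2.2)
vt = simulate_measurements(EphysSimSpec(
    "vrev_series", {"n": 2.2, "na_o": 100, "na_i": 10, "s_i": 0.05},
    np.geomspace(1, 100, 6), replicates=10, noise_sigma=1.0, seed=3))
est = coupling_ratio_from_vrev(vt["x"], vt["response"], ThermoContext())
print(f"n = {est.n:.2f} +/- {est.n_se:.2f}")
# n = 2.17 +/- 0.02            (slope 11.72 mV per ln-unit of sugar)

# build and inspect a Na3-like coordination site
st = make_site_fixture(SiteFixtureSpec(geometry="na3_motif"))
site = classify_contacts(detect_na_sites(st, entry_id="demo")[0], st)
print(site.coordination_number, site.bidentate_residues,
      has_serthr_adjacent(site))
# 5 [('A', 204, 'ASP')] True
```

The fitted affinity and coupling ratio land within a few percent of the
generating values; the synthetic Na3-style site is five-coordinate with a
bidentate aspartate and a Thr/Ser pair at consecutive residue numbers,
which is exactly what the census and similarity tools are built to detect.

The same operations are available on the command line:

```
symport simulate site --geometry na3_motif -o na3.pdb
symport census na3.pdb
symport fit hill currents.csv
symport stoichiometry from-vrev vrev.csv
symport report selectivity
```

A transcription of the measured per-construct parameter table (apparent
affinities and inhibition constants for hSGLT1, hSGLT2 and hSGLT1 mutants)
ships with the package, so `symport report selectivity` reproduces the
mutant fold-changes and subtype-selectivity ratios offline.

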