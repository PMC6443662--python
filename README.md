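# ubfret

Quantitative analysis of ubiquitin-chain conformational dynamics by
single-molecule FRET and NMR, built around a conformational-selection
study of K48-linked diubiquitin (K48-diUb) binding to the proteasomal
receptor Rpn13.

K48-diUb in solution is not a single structure: it fluctuates among a
compact, a semi-open and an open arrangement of its two ubiquitin
subunits. With a donor/acceptor pair (Alexa488/Cy5, Förster distance
R₀ = 52 Å) conjugated across the two subunits, each conformational state
appears as a Gaussian peak in the distribution of per-burst FRET
efficiencies, and a binding partner that prefers one state shifts the
peak populations without moving the peak centers. This package implements
the full numerical pipeline for that style of experiment:

* **bursts** — binning photon arrival times (1-ms bins), per-bin threshold
  burst detection (3–10 counts/bin), PIE-based donor-only filtering, and
  the proximity-ratio efficiency E = n_A/(n_A + γ·n_D);
* **mixture** — expectation-maximization fitting of K-component Gaussian
  mixtures to burst efficiencies, with BIC/AIC model selection
  (k_params = 3K − 1), histogram R² as a secondary diagnostic, and
  triplicate averaging of replicate fits;
* **binding** — the exact (ligand-depletion) two-state isotherm
  ΔP(C) = P_max·(S − √(S² − 4·C·C_diUb))/(2·C_diUb), S = C + C_diUb + K_D,
  evaluated in a numerically stable form and fit by nonlinear least
  squares for K_D and P_max, plus competition (percent inhibition) and
  affinity fold-change arithmetic;
* **forster** — E ↔ r conversion via E = 1/(1 + (r/R₀)⁶) and ensemble
  back-calculation from multi-model PDB coordinates with both ⟨E⟩ and
  ⟨r⁻⁶⟩-based averaging;
* **nmr** — chemical shift perturbations Δδ = [0.5(Δδ_H² + 0.2Δδ_N²)]^½,
  two-time-point PRE rates Γ₂, and interface / PRE-hot residue calling;
* **synthetic** — generators for every input above (burst efficiencies,
  photon traces, titrations, distance ensembles, CSP/PRE tables) so the
  entire pipeline is testable without instrument data.

## Worked example

Simulate 5,000 bursts from the three-state K48-diUb model (compact 0.74,
semi-open 0.57, open 0.23 at populations 48/39/13%), decompose them, and
convert the high-FRET center to a distance:

```python
import numpy as np
from ubfret import (StateModel, SimConfig, gen_burst_efficiencies,
                    select_k, distance_from_efficiency)

model = StateModel.diub_76c_0c()
cfg = SimConfig(n_bursts=5000, seed=3, noise_model="gaussian")
eff = gen_burst_efficiencies(model, cfg)["efficiency"]

best_k, fits = select_k(eff, range(1, 6), criterion="bic", seed=3)
fit = next(f for f in fits if f.k == best_k)
print(best_k, np.round(fit.centers, 3), np.round(fit.weights, 3))
print(round(distance_from_efficiency(fit.centers[0]), 1))
```

prints

```
3 [0.743 0.57  0.237] [0.476 0.394 0.13 ]
43.6
```

i.e. BIC selects three species, the recovered centers/populations match
the generating model, and the compact state sits ~43–44 Å between dye
centers. The same steps are available from the shell:

```bash
ubfret simulate bursts --n-bursts 5000 --seed 3 --out bursts.tsv
ubfret fit-mixture bursts.tsv --select-k 1:5 --criterion bic --seed 3
ubfret fret-calc --efficiency 0.74
ubfret compete --enrichment 15 --decrease 7.5
```

Titration fitting works the same way: `ubfret simulate titration --kd
33.1nM --out t.tsv` then `ubfret fit-titration t.tsv --c-diub 150pM
--baseline 48` recovers K_D = 33.1 nM with asymptotic errors.

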