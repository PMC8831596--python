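# flexfold

Integrative, restraint-based determination of **flexible, C5-symmetric
membrane-protein domains** from solution-NMR and ESR observables — built
around the problem of solving the large, mostly disordered intracellular
domain (ICD) of pentameric ligand-gated ion channels such as the human α7
nicotinic acetylcholine receptor, a domain that neither crystallography nor
cryo-EM can resolve.

The package implements the full desk-scale pipeline:

1. **Observable → restraint conversion**
   - Paramagnetic relaxation enhancement (PRE): intensity ratios *I/I₀* and
     diamagnetic linewidths → transverse enhancement rates *R₂^sp* →
     label–amide distances via the Solomon–Bloembergen relation
     *r = [(K/R₂^sp)(4τc + 3τc/(1+ω_H²τc²))]^(1/6)*, with ratio
     floor/ceiling rules producing bound-only restraints outside the
     sensitive window.
   - DEER distance distributions *P(r)*: two-Gaussian decomposition with the
     pentagon constraint *d_diag/d_adj = 2 cos 36° ≈ 1.618* into
     adjacent/diagonal inter-subunit harmonic restraints.
   - NOE cross-peak classes → flat-bottom bounds; IPAP ¹⁵N splittings →
     RDCs; amide-shift temperature coefficients (|Δδ/ΔT| < 4.5 ppb/K ⇒
     hydrogen bonded); R₁/R₂ exponential fits and ¹⁵N–(¹H) heteronuclear
     NOEs for backbone dynamics.
2. **Restraint-scored, C5-symmetric ensemble folding** — Metropolis
   simulated annealing of one subunit (rigid helices, flexible loops),
   scored on the implied pentamer with
   *S_total = S_physics + S_knowledge + S_DEER (harmonic) + S_PRE (sigmoid)
   + S_NOE (flat-bottom)*, inside an iterative
   generate → rank → cluster (greedy leader, 3 Å Cα-RMSD cutoff) → reseed
   protocol with first-round homolog templates.
3. **Validation and structural analytics** — Q-factors
   *Q = √(Σ(r_exp − r_calc)² / Σ r_exp²)* per restraint class with a
   held-out PRE free set, hydrogen-bond-pattern secondary structure,
   disorder fractions, pore-radius profiles along the channel axis, lateral
   portal bottlenecks and salt-bridge distances.
4. **A synthetic-data generator** — a toy 60-residue/subunit C5 pentamer
   (short amphipathic helix, large anchored loop, long membrane-associated
   helix) whose forward models emit every observable the pipeline consumes,
   so the whole workflow runs and is testable at desk scale.

## Worked example

```python
import numpy as np
from flexfold.synthetic import make_bundle, restraints_from_bundle
from flexfold.protocol import ProtocolConfig, run_protocol
from flexfold.validation import holdout_split, q_report
from flexfold.structio import Ensemble, ca_rmsd

bundle = make_bundle(0)                      # toy pentamer + observables
restraints = restraints_from_bundle(bundle)  # 446 restraints (PRE/DEER/NOE)

pre = [r for r in restraints if r.kind == "PRE"]
other = [r for r in restraints if r.kind != "PRE"]
working_pre, free = holdout_split(pre, 0.1, seed=0)   # 10% PRE holdout

result = run_protocol(
    ProtocolConfig(master_seed=0),           # pool 40, top 10, <=6 iterations
    other + working_pre, bundle.truth.ss, bundle.truth.residue_numbers,
    templates0=[bundle.template_subunit],    # homolog template, round 1 only
)
print("converged:", result.converged)
print("recovery RMSD (Å):",
      round(ca_rmsd(result.final.models[0], bundle.truth.structure), 2))
report = q_report(Ensemble(models=result.final.models),
                  {"PRE": working_pre}, free)
print("Q_PRE_free:", round(report.q_pre_free, 3))
```

Output:

```
converged: True
recovery RMSD (Å): 3.12
Q_PRE_free: 0.056
```

i.e. the protocol converges in four iterations and the best model lies
3.1 Å Cα RMSD from the generating ground truth, with the held-out PRE
restraints back-calculated to a free Q-factor of 0.056 (a Q of 0 would be
perfect agreement; values well below ~0.3 indicate the held-out distances
are predicted, not merely fitted).

A command-line interface mirrors the library:

```bash
flexfold simulate --seed 7 --out bundle/     # write a synthetic bundle
flexfold protocol --seed 0 --out run/        # iterative folding
flexfold pore --in run/final_ensemble.pdb    # pore-radius profile
flexfold qreport --in run/final_ensemble.pdb --restraints restraints.tsv
```

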