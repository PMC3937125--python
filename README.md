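# micffl

Deterministic and stochastic analysis of **miRNA-controlled feed-forward
loops** (micFFLs) — the motif in which a miRNA represses both a
transcription factor (TF) and a target gene (T) that the TF activates —
together with the genome-scale machinery for finding and scoring such
motifs in regulatory networks.

The package is aimed at systems biologists studying post-transcriptional
regulation: it answers how the titrative miRNA–mRNA interaction (the
"sponge effect") lets a miRNA fine-tune the ratio of its two targets, how
the closed-loop topology stabilizes that ratio against stochastic
fluctuations, where the titration threshold sits, and how to test whether
the motif is over- or under-represented in an observed network.

## The model

The circuit couples transcriptional activation with titration:

```
dmTF/dt = k_mTF − g_mTF·mTF − k_on·mi·mTF
dpTF/dt = k_pTF·mTF − g_pTF·pTF
dmT/dt  = k_mT·pTF^n/(pTF^n + h^n) − g_mT·mT − k_on·mi·mT
dpT/dt  = k_pT·mT − g_pT·pT
dc/dt   = k_on·mi·m − g_c·c            (one complex per titrated mRNA)
dmi/dt  = k_mi − g_mi·mi − Σ k_on·mi·m + α·Σ g_c·c
```

The miRNA and an mRNA interact only by forming a complex that eventually
degrades, recycling the miRNA with probability α. Five null models (NM1 —
direct regulation only; NM2/NM3 — one miRNA link each; NM4 — no TF→T
link; NM5 — two independent miRNAs) isolate which behaviours come from
titration and which from the loop topology. All rates are dimensionless
(time in target-protein lifetimes).

Layers of analysis, one module each:

* `micffl.circuits` — topologies, kinetic parameters, reaction systems;
* `micffl.deterministic` — closed-form steady states, total↔free miRNA
  inversion, ratio curves r(mi_tot) = pT*/pTF*, ODE integration,
  switch-on/off response times;
* `micffl.stochastic` — Gillespie direct-method simulation (numba),
  stationary moments and the TF–T correlation ρ(pTF, pT);
* `micffl.lna` — linear noise approximation (Lyapunov covariance),
  correlation heat maps over (miRNA transcription, interaction strength),
  threshold/hypersensitivity analysis;
* `micffl.motif_mining` — micFFL enumeration from edge lists,
  degree-preserving layer shuffles with z-scores, PWM promoter scanning,
  binomial overlap test;
* `micffl.synthetic_data` — generators for networks with planted (or
  depleted) motifs, physiological kinetic parameters, and promoters with
  embedded motif sites.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Fine-tuning of the target/TF ratio as the total miRNA pool grows:

```python
from micffl import KineticParameters, solve_steady_state

p = KineticParameters()          # dimensionless physiological defaults
for mi_tot in (0, 10, 20, 40):
    ss = solve_steady_state(mi_tot, p, "MICFFL")
    print(f"mi_tot={mi_tot:>3}  free={ss.free_mirna[0]:6.2f}  "
          f"pTF={ss['pTF']:6.2f}  pT={ss['pT']:6.2f}  r={ss.ratio:.3f}")
```

```
mi_tot=  0  free=  0.00  pTF= 20.00  pT= 19.95  r=0.998
mi_tot= 10  free=  4.23  pTF= 17.11  pT= 17.05  r=0.997
mi_tot= 20  free=  9.24  pTF= 14.60  pT= 14.54  r=0.995
mi_tot= 40  free= 21.56  pTF= 10.74  pT= 10.65  r=0.991
```

Both proteins are titrated down while their ratio r barely moves — the
symmetric repression that makes the motif a ratio stabilizer (with
asymmetric binding rates the same dial retunes r to any value). The
titration threshold of the open motif NM4 sits at the equimolarity point,
where miRNA production balances its targets' summed transcription:

```python
import numpy as np
from micffl import threshold_analysis
from micffl.circuits import with_interaction_strength

res = threshold_analysis(with_interaction_strength(p, 100.0), "NM4",
                         np.geomspace(1, 120, 160))
print(f"NM4 threshold: {res.crossover:.1f} (equimolar flux {res.equimolar:.1f})")
# NM4 threshold: 30.2 (equimolar flux 30.0)
```

Enrichment testing on a synthetic network with 200 planted micFFLs
(degree-preserving miRNA-layer shuffle, 200 permutations):

```python
from micffl import NetworkSpec, generate_network, enrichment_test

net, truth = generate_network(NetworkSpec(n_planted_ffls=200, seed=1))
res = enrichment_test(net, "mirna", n_perm=200, min_support=4, seed=2)
print(f"observed micFFLs: {res.n_real}, null {res.null_mean:.1f} "
      f"+/- {res.null_sd:.1f}, z = {res.z:.1f}")
# observed micFFLs: 319, null 12.6 +/- 4.6, z = 66.3
```

The planted signal is recovered as a strongly positive z-score; a network
from which every closing TF→T edge has been removed gives the mirror-image
strongly negative z-score under the TF-layer shuffle.

A `micffl` command-line tool wraps the stages (`steady-state`,
`ratio-curve`, `response-times`, `ssa`, `lna-heatmap`, `threshold`,
`enumerate`, `enrich`, `scan-pwm`, `make-fixtures`); every run writes its
numerical outputs plus a manifest with input hashes, the seed and the
package version.

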