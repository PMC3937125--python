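# Methods

This note documents the models implemented in `micffl`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## The circuit model

The central object is a three-node motif in which a miRNA represses both a
transcription factor (TF) and a target gene (T) that the TF
transcriptionally activates — a feed-forward loop with the miRNA as master
regulator (micFFL). Species: free miRNA `mi`, TF mRNA `mTF` and protein
`pTF`, target mRNA `mT` and protein `pT`, and the miRNA–mRNA complexes
`cTF`, `cT`.

Reactions (mass action unless noted):

* constitutive transcription of the miRNA (rate `k_mi`) and of `mTF`
  (`k_mtf`); target transcription follows the activatory Hill function
  `k_mt · pTF^n / (pTF^n + h^n)` when the TF→T link is present;
* translation `k_p · m` and first-order degradation of every free species;
* titration: `mi + m → c` at rate `k_on · mi · m`. The complex never
  dissociates; it degrades at rate `g_c`, releasing the miRNA intact with
  recycling probability `α` (implemented as two competing degradation
  channels with rates `α·g_c` and `(1−α)·g_c`, which is equivalent in law
  and keeps every propensity elementary). With `α = 1` and no miRNA
  turnover the total pool `mi + cTF + cT` is strictly conserved — an
  invariant asserted event-wise in the stochastic tests.

Five null models delete interactions from the micFFL: NM1 (direct TF→T
regulation only, no miRNA), NM2 (miRNA→TF only), NM3 (miRNA→T only), NM4
(both miRNA links but no TF→T link) and NM5 (TF→T plus two *independent*
miRNA species with identical kinetics, one per target). When the TF→T link
is absent (NM4) the target promoter transcribes at its TF-independent basal
activity, parameterized as a fraction `basal` of the Hill maximum (default
0.5, the midpoint of the promoter's activity range). This choice makes the
TF link an *activation above basal*: closing the loop raises the effective
target transcription rate, which is what shifts the micFFL titration
threshold above NM4's (see below).

All rates are dimensionless, rescaled by the target-protein degradation
rate (`rescale_parameters`); time is measured in target-protein lifetimes.

### Default parameters

Defaults place the circuit in a physiological regime (a few mRNAs, tens of
proteins per cell at volume `Ω = 1`; mRNAs ~5× less stable than proteins):

| parameter | default | meaning |
|---|---|---|
| `k_mtf`, `k_mt` | 20 | mRNA transcription (molecules/lifetime) |
| `k_ptf`, `k_pt` | 5 | translation per mRNA |
| `g_mtf`, `g_mt` | 5 | mRNA degradation |
| `g_ptf`, `g_pt` | 1 | protein degradation (`g_pt` is the time unit) |
| `k_mi`, `g_mi` | 20, 1 | miRNA transcription / degradation |
| `g_ctf`, `g_ct` | 1 | complex degradation |
| `k_on` | 0.2 | titration rate (per molecule per lifetime) |
| `α` | 0 | recycling probability |
| `n`, `h` | 2, 1 | Hill coefficient / activation coefficient |
| `basal` | 0.5 | unregulated promoter activity (NM4) |

The miRNA-free steady state is then `pTF⁰ = 20`, `pT⁰ ≈ 19.8`. `h = 1 =
pTF⁰/20` puts the Hill function deep in saturation at the operating point,
the regime the steady-state theory assumes; the TF→T coupling only becomes
dynamically visible when titration drives `pTF` down toward `h`. The
miRNA–mRNA interaction strength is summarized as `F = k_on / g_c`
(`interaction_strength`); the published compound expression is not
available in the source text, so the definition is exposed as a replaceable
callable and `F` is used purely as a sweep axis.

## Deterministic theory

Given the free miRNA level `mi`, every other species' fixed point is in
closed form (`steady_state_given_free_mirna`); the Hill input is evaluated
at the repressed `pTF*(mi)`, so the closed form remains exact without
linearization. Two inversions connect `mi` to experimentally meaningful
drives:

* **conserved pool** — total miRNA `mi_tot = mi + cTF* + cT*` (the dial of
  the ratio-curve analysis); inverted by bracketed root finding on
  `[0, mi_tot]`, a valid bracket because sequestration is non-negative;
* **transcriptional drive** — flux balance
  `k_mi = g_mi·mi + (1−α)·Σ k_on·mi·m*` (the dial of the stochastic, LNA
  and threshold analyses).

At strong interaction the micFFL's flux balance is *not* monotone in `mi`:
repressing the TF collapses the Hill input and with it the miRNA's own
consumption, producing a fold. Both inversions therefore select the
smallest root — the branch continuously connected to the miRNA-free state,
i.e. the state occupied under an adiabatic sweep of the drive. The jump at
the fold is the micFFL's threshold.

**Ratio curves.** `r(mi_tot) = pT*/pTF*` starts at `r₀ = pT⁰/pTF⁰` and is
tuned downward by the miRNA. NM2 (TF repressed only) tunes `r` up, NM3
(target repressed only) tunes it down, and the micFFL curve lies between
them; the curve steepens with the Hill coefficient, quantified as the
maximal logarithmic slope `|d log r / d log mi_tot|` (the absolute slope
conflates this with the early slope of weakly saturated low-`n` curves).
Regions where either protein falls below 5% of its miRNA-free value are
masked as "almost absent" (configurable threshold); claims about the
curves are made outside those masks, where they are clean — inside them
`H(p)/p` turns over at `p = h·(n−1)^{1/n}` and the NM2 curve reverses.

**Threshold analysis.** Along a `k_mi` grid, `threshold_analysis` reports
(i) the point of maximal logarithmic sensitivity `|d log pT*/d log k_mi|`
(the threshold; quadratically refined around the grid maximum), (ii) the
half-repression point `pT* = pT⁰/2`, and (iii) the near-equimolarity
reference `(1−α)·(k_mtf + k_t,eff)` at which miRNA production balances the
summed transcription of its targets. In the strong-interaction limit the
NM4 threshold sits at the equimolarity point (within ~1% at `F = 100`);
the micFFL threshold sits higher because the activated target transcribes
above NM4's basal rate. The half-repression point is *not* the threshold:
for near-symmetric parameters it sits near half the equimolar flux, well
below the hypersensitive kink.

**Response times.** `T_on` (`T_off`) is the time for `pT` to reach half
its final (initial) steady level after TF transcription switches on (off).
The comparison against NM1 follows a like-for-like protocol: `k_mtf` and
`k_mt` of the miRNA circuit are rescaled (damped multiplicative fixed
point, then a root polish) so that both protein steady levels equal the
NM1 reference. The default miRNA treatment is *clamped*: the free pool is
held at `k_mi/g_mi` as an external input, so titration acts as an extra
first-order mRNA decay channel — consistent with the deterministic
analysis, where the miRNA amount is the control dial. A `dynamic` mode
evolving the full miRNA balance through the switch is also provided. Under
the clamped protocol the switch-on ratio falls monotonically below 1 (the
faster effective mRNA turnover at matched steady states shortens the
transient); the switch-off ratio stays within ~10% of NM1 and decreases
mildly. We could not construct any titration-consistent protocol in which
the switch-off time *increases* with the miRNA level: sequestration can
only shorten the persistence of the target mRNA after switch-off. The
corresponding acceptance check is therefore expected to fail and is left
failing rather than weakened.

## Stochastic simulation and the linear noise approximation

`gillespie` implements the direct method over the compiled reaction list
(numba kernel; bitwise-reproducible given a seed), with grid-sampled or
event-wise recording. Stationary moments use sample means over the
post-burn-in grid with batch-means standard errors (20 batches by
default); the default burn-in is 10× the slowest relaxation time of the
drift Jacobian. The Hill propensity is evaluated exactly in simulation —
linearization is purely an LNA device — which makes the SSA the
independent oracle for the LNA.

The LNA solves `A·C + C·Aᵀ + B = 0` with `A` the drift Jacobian at the
driven fixed point (the Hill enters through its tangent at `pTF*`,
`linearize_hill`) and `B = Σ ν νᵀ a(x*)` the standard diffusion matrix;
the Lyapunov equation is solved densely (system dimension ≤ 8) and the
residual is required to be < 1e-6 relative. Unstable or degenerate fixed
points raise and are recorded as missing heat-map cells. The Pearson
correlation ρ(pTF, pT) derived from `C` matches the SSA estimate to within
0.05 on a 4×4 (`k_mi` × `F`) grid at volume Ω = 100 (10 seeds, 400 time
units of sampling per run); agreement of mean copy numbers tightens as Ω
grows, as the system-size expansion predicts.

**Heat-map pattern.** On (`k_mi`, `F`) grids, restricted to the expressed
regime (both proteins above 5% of their miRNA-free levels, the same rule
as the ratio-curve masks): NM3 is flat at the NM1 direct-regulation
baseline (deviation < 0.01 — at saturation the Hill tangent is nearly
zero); micFFL and NM4 show a contiguous high-correlation band along the
miRNA axis (the sponge effect, strongest near the threshold) across the
stronger half of the `F` range; NM5 carries the direct-link contribution
that appears once titration pushes `pTF` into the sensitive part of the
Hill curve; and the micFFL profile approximates the cell-wise union of the
NM4 (sponge) and NM5 (direct-link) profiles while attaining, for every
`F`, a higher maximum than NM4. The fluctuation maximum (coefficient of
variation of `pT` over the expressed regime) co-locates with the
hypersensitive band.

## Motif mining

The mining layer consumes generic TSV edge lists: a miRNA→gene layer with
a per-edge support count (how many of up to four interaction databases
confirm the edge) and a TF→gene layer. `enumerate_micffls` joins the two
layers (pandas merges) into (miRNA, TF, target) triples with `TF ≠
target`, filtered by minimum miRNA-link support; the join is verified
against a brute-force triple loop. Enrichment reshuffles one layer at a
time, preserving each regulator's out-degree exactly (targets resampled
uniformly without replacement from the declared gene universe) and leaving
the other layer untouched; `z = (N_real − μ)/σ` over the permutation null
(default 1000 permutations), with add-one-corrected empirical tail
p-values. Shuffled miRNA edges carry maximal support so that the support
filter constrains only the observed network, not the null. A degenerate
null (σ = 0) yields a flagged result instead of a z-score.

PWM scanning builds log-odds scores from pseudocounted position
frequencies (pseudocount 1 per cell, uniform background — both
configurable) against a uniform background, and reports windows whose
relative score `(s − s_min)/(s_max − s_min)` exceeds the threshold
(default 0.7); windows containing `N` are skipped. JASPAR matrices are
parsed with Bio.motifs, and the scoring matrix is cross-checked against
Biopython's PSSM in the tests. Promoter windows are 1 kb, from 900 bases
upstream to 100 bases downstream of the TSS, 0-based half-open,
strand-mirrored, clipped (and flagged) at coordinate 0. The overlap of
candidate TF–target pairs with an external protein-interaction catalogue
is assessed with an upper-tail binomial test.

## Synthetic data

The generators are pure functions of (spec, seed) and always emit a
ground-truth side channel:

* **Networks** — two bipartite layers over a universe of TF and gene ids;
  out-degrees per layer are fixed, Poisson, or power-law (default:
  power-law exponent 2 for miRNA targetomes, Poisson for TFs — real
  degree data being unavailable, these are generic heavy-tailed/homogeneous
  choices). micFFLs are planted by closing TF→T edges over co-targeted
  pairs (planted edges get maximal support); depletion instead removes
  *every* closing TF→T edge. Planted-signal study conditions: 200 planted
  loops on the default background for the positive control; a denser
  co-targeting regime (40 miRNAs × Poisson(25), 15 TFs × Poisson(40), 300
  genes) for the depletion control, sized so the permutation null expects
  ~100 loops and the depletion signal is unambiguous. The generator does
  not model sequence-level seed matching, conservation, or correlated
  evidence between databases; recovery tests therefore validate the
  *machinery* (counting, degree-preserving nulls, sign of enrichment), not
  biological realism of the edge structure.
* **Kinetic parameters** — log-uniform draws per rate class over
  physiological dimensionless ranges, rejection-sampled so the miRNA-free
  steady state has 10–10⁵ protein copies; a bounded retry budget turns
  pathological range choices into an explicit error.
* **Promoters** — i.i.d. background of configurable GC content with motif
  occurrences (consensus or PFM-sampled) embedded at known positions and
  strands; embeddings may not overlap. Background hits can still occur by
  chance, so recovery tests assert containment of the truth, not equality.

## Numerical choices

* ODE integration: LSODA with tight tolerances; closed-form fixed points
  agree with `t → ∞` endpoints to better than 1e-6 relative over a
  50-point Latin hypercube × 6 topologies (integration horizon 45× the
  slowest relaxation time).
* Root finding: first-crossing scan (256 geometric points) + Brent
  polish, `xtol = 1e-14`; inversion round-trips are exact to ~1e-12.
* Problem sizes in the shipped checks (SSA grid sizes, seed counts,
  permutation counts, LHS size) are chosen so each standard error is
  several times smaller than the tolerance it guards.
* Ties/degenerate inputs: absorbing SSA states end the trajectory with a
  flag; constant trajectories flag their undefined correlation; σ = 0
  permutation nulls flag the z-score; PWM scans of short or all-`N`
  sequences return empty flagged results.

## Known limitations

* Promoter-state (on/off gene) dynamics and TF self-regulation are not
  modelled.
* The interaction-strength compound `F = k_on/g_c` is a stand-in
  definition; results using `F` as an axis are qualitative in `F`.
* The LNA degrades exactly at the fold (marginally stable Jacobian);
  heat-map cells there are still reported but carry the largest error.
* No protocol consistent with the titration model yields a switch-off
  time that increases with the miRNA level (see Response times above);
  the corresponding expectation in the test suite is left failing.
* Tau-leaping/hybrid acceleration and spatial effects are out of scope.
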