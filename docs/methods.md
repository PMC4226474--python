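# Methods

`pegtether` models a ligand tethered to a rigid surface by a flexible
poly(ethylene glycol) (PEG) linker and asks how the linker's length shapes
(i) the ligand's average distance from the surface, (ii) the kinetics of its
binding to an apposed surface, and (iii) downstream cell-activation trends.
This note records the models, the parameter choices, and what the synthetic
data do and do not establish.

## Polymer descriptors

A PEG of molecular weight `MW` is a chain of `n = MW / 44` ethylene-oxide
units of projected length `a = 0.28` nm in water. The package reports

- contour length `L_c = n a` (nm),
- Flory radius `R_F = a n^{3/5}` (nm), the equilibrium coil size of a
  self-avoiding chain in good solvent,
- the Gaussian-chain entropic force `f = 3 kT x / (n a^2)` (pN) at
  end-to-end extension `x`, valid well below `L_c`,
- a Rouse estimate of the longest relaxation time,
  `tau_1 ≈ b^2 N^2 / (3 π^2 D)`, used only to size simulations.

The *unrounded* unit count is used for `L_c` and `R_F`; the integer count is
display-only (this is what reproduces the reference table's printed values,
e.g. 79.55 × 0.28 = 22.3 nm for the 3500 Da linker, not 80 × 0.28 = 22.4).
Printed values are compared after rounding half-up to one decimal. Thermal
energy defaults to `kT = 4.11` pN·nm (300 K). One caveat: for the 88 Da
linker (n = 2) the formula gives `R_F = 0.42 → 0.4` nm while the reference
table prints 0.5 nm; no rounding convention reconciles the two, so the
package reports the formula value and ships the printed table unchanged as
a fixture.

## FRET tether-distance model

The donor sits on the ligand, the acceptor on the surface. The expected
donor–acceptor distance is `r = R_F + r_ligand` with `r_ligand = 2` nm, and
transfer efficiency follows the Förster form `E = 1 / (1 + (r/R_0)^6)` with
`R_0 = 5` nm (DyLight 549/649). Measured efficiencies use the acceptor
photobleaching estimator `E = 1 − I_before / I_after`; negative estimates
(possible under noise) are clamped to zero and flagged rather than
propagated, a choice the source experiment leaves open. Series are compared
after normalising by the shortest linker present. Linkers whose transfer is
below detection are represented as missing, never as zero.

## Tethered-chain Brownian dynamics

The binding simulation replaces the original coarse-grained lipid-bilayer
system with the minimal mechanism it probes: chain entropy and steric
access. A bead-spring chain (one bead per 3 PEO units, so segment length
`b = 0.84` nm) is fixed at one end `h = 9` nm above a plane; the terminal
bead alone feels a Gaussian attractive well at the plane
(`U = −ε exp(−z²/2s²)`, depth `ε = 7 kT`, `s = 0.5` nm so the well range
matches the 1 nm binding cutoff). All beads feel

- harmonic bonds (`k_bond = 100 kT/nm²`),
- a bounded soft-core repulsion `U = ε_ev (1 − r/σ)²` for `r < σ` with
  `σ = b` and `ε_ev = 25 kT` between non-bonded pairs. The bounded force
  (unlike WCA) keeps the explicit Euler–Maruyama step stable at any contact
  distance while the 25 kT overlap penalty makes chain crossings negligible;
  the measured end-to-end scaling exponent (~0.60) confirms self-avoiding
  statistics,
- a soft half-harmonic wall below `z = 0` (`k_wall = 200 kT/nm²`), which
  admits ~0.1 nm penetration (`√(kT/k_wall)`); height invariants are stated
  up to this softness tolerance.

Dynamics are overdamped Langevin steps `dx = D F dt + √(2 D dt) η` with
`kT = 1` internally and bead diffusion `D = 1 nm²/τ` defining the reduced
time unit; no calibration to physical nanoseconds is attempted, so only
rate *ratios* across chain lengths are meaningful — which is also how the
original study reports its simulated rates (scaled to the shortest
polymer). The timestep `dt = 0.003 τ` is validated at construction: the
per-step RMS displacement must stay below 0.1 × the binding range so the
well is diffusively resolved. Each replica grows its own initial
conformation (random walk with overlap rejection) and integrates from an
independent seed spawned off one master seed; identical seeds are
bit-reproducible. Ten Rouse times of equilibration are discarded.

Binding events are detected with a dual cutoff — bind when the terminal
height drops below 1 nm, unbind when it exceeds 1.5 nm — to suppress
recrossing chatter at the threshold; the single-cutoff definition used by
the original study is available as a fidelity mode. First and last dwells
are censored.

## Kinetics and PMF

Rates are mean-first-passage estimates, `k_on = 1/⟨t_unbound⟩`,
`k_off = 1/⟨t_bound⟩`, over complete dwells pooled across replicas, with
seeded percentile-bootstrap intervals (default 1000 resamples). A
censoring-aware exponential-MLE variant (completed events / total observed
time in state) is provided as a cross-check; for short traces dominated by
censored waits the MFPT estimator is biased toward faster rates, which is
why sweep production times are sized to tens of complete events per length.

The potential of mean force along the terminal height is the histogram
estimator `W(z) = −kT ln p(z)` (bin width 0.1 nm, minimum shifted to zero,
empty bins masked; a histogram rather than a kernel estimator for
transparency). The most probable binding distance is the minimum of `W`
inside the bound region. The *force at the most probable binding distance*
is the central-difference slope `−dW/dz` there, after subtracting the known
external potential on the terminal bead (binding well plus wall): the
remaining slope is the tether's chain-entropy contribution — the pull the
polymer applies to the bond — which is the physically meaningful analogue
of the original study's PMF-derived force. On the raw profile that slope is
zero at a minimum by construction, which is the behaviour exercised by the
harmonic-well test.

## Study-scale choices

The chain-length sweep uses 15, 30 and 60 beads (20 replicas each,
`ε = 7 kT`, `h = 9` nm) with production durations of 8000, 2500 and 2500 τ
per replica respectively — sized so each length accumulates enough complete
binding events for stable rate ordering; the short chain binds rarely
(it must stretch to ~70% of its contour to reach the plane) and therefore
needs the longest observation window. Rates are scaled against the
15-bead chain.

A consequence of this geometry is worth stating plainly: at fixed tether
height, the simulated **on-rate increases with chain length** (the short
chain pays a large entropic stretching penalty to reach the plane, the long
chain's coil radius is comparable to the tether height), while the
**off-rate decreases with length** and the tether force at the binding
distance is non-increasing — the longer chain pulls less hard on the bond,
exactly the Gaussian-chain `f ∝ 1/n` behaviour. The off-rate and force
trends reproduce the original study's findings; the on-rate trend does not.
The original simulations reported both rates decreasing with length,
attributing the on-rate drop to steric shielding by the longer chains; in
this implicit-surface model, with the mechanisms retained here (chain
entropy, excluded volume, wall sterics), the accessibility gain of longer
chains dominates any self-shielding. The corresponding acceptance check is
left failing rather than adjusted, because it is a genuine disagreement
between the reduced model and the original (unpublished-in-detail)
simulation scheme, not a software defect.

## Synthetic data

The generators provide ground truth for closed-loop tests:

- **Telegraph traces**: alternating exponential dwells at known rates, plus
  a surrogate height series (0.5 nm bound / 3.0 nm unbound, 0.05 nm jitter)
  whose levels sit far from both detection cutoffs, so single- and
  dual-cutoff detection recover the generator's dwell bookkeeping exactly.
  They emulate two-state switching only — no diffusive approach dynamics,
  no recrossing, no censoring ambiguity — so passing recovery tests
  validates the estimators, not the simulator.
- **FRET intensity pairs**: post-bleach donor intensities around a base
  level with 10% spread; pre-bleach = post-bleach × (1−E) with
  multiplicative Gaussian noise (default 5%). Real photobleaching drift and
  background subtraction are not emulated.
- **Response curves**: linear-in-time normalized IL2 responses (default six
  hourly timepoints, three experiments, additive noise sd 0.02, clipped to
  [0, 1]; at default settings the clipping attenuates fitted slopes by well
  under 1%). Real dose–response saturation and inter-animal variability are
  not emulated.

Passing on these generators shows the estimators are correct under the
stated noise models; it does not validate the noise models against real
instruments.

## Known limitations

- Reduced time units preclude absolute rates; only cross-length ratios are
  interpretable.
- The implicit plane omits bilayer fluctuations, lipid specificity and
  protein geometry; the ~40 pN force of the original study is therefore a
  qualitative magnitude here (the model yields ~16 pN for its shortest
  sweep chain), not a reproduced number.
- The MFPT estimator over complete dwells is length-biased when dwells are
  comparable to the observation window; the exponential-MLE cross-check
  mitigates but production sizing is the real control.
- The 10 µM affinity of the original ligand–receptor pair cannot be mapped
  uniquely onto a well depth in this geometry; `ε = 7 kT` is a fixed model
  constant, not a fitted value.
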