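# Methods

## Model

Two reversible mass-action reactions control the free concentration of an
active RNA ("agent" A): sequestration by an inhibitor X and neutralisation
of the inhibitor by an anti-inhibitor Y,

    A + X ⇌ AX   (k1, k2),    X + Y ⇌ XY   (k3, k4),

giving five coupled ODEs for [A], [X], [Y], [AX], [XY] with conserved
totals cA, cX, cY.  Concentrations are dimensionless (the source studies
give no units); all worked numbers are used as printed.

**Equilibrium.**  Substituting the conservation relations into the
equilibrium conditions K[AX] = [A][X], k[XY] = [X][Y] (K = k2/k1,
k = k4/k3) reduces the problem to one unknown x = [A]: a quadratic when
cY = 0, otherwise the cubic L(x) with coefficients

    a = k − K
    b = (k − K)(cX + K − cA) + K(cA + cY)
    c = K cA (2K − k − cA + cX − cY)
    d = −K² cA².

L(0) = −K²cA² < 0 and L(cA) = k·cX·cA² > 0, so a single root lies in
(0, cA); a Lyapunov argument (below) shows the equilibrium is unique, and
the root reconstructs the full state via [X] = K(cA−x)/x, [AX] = cA−x,
[Y] = [X]+cA−x−cX+cY, [XY] = cY−[Y].

**Capacity.**  β = 1/(∂x/∂cA) is the buffering factor of the control
loop.  Differentiating L(x(cA)) = 0 gives the closed form
β = (3a x² + 2b x + c)/(e x² + f x + g) with e = k−2K,
f = −K(2K−k−2cA+cX−cY), g = 2K²cA, bounded by 0 < β < cA/x (and
1 < β < cA/x in the anti-inhibitor-free model, where
β = (x²+KcA)/(x²+Kx)).  The test suite verifies both closed forms against
central finite differences of the respective equilibrium solvers
(relative 1e-4), i.e. against the definition.

**Stability.**  With deviations x = [A]−x0, y = [Y]−y0 from equilibrium,
V = k3 y0 x² + k1 x0 y² is positive definite and its total derivative
along trajectories,

    dV/dt = −2k2k3 y0 x² − 2k1k4 x0 y² − 2k1k3 x0 y0 (x+y)²
            − 2k1k3 (y0 x² + x0 y²)[X],

is nonpositive and vanishes only at equilibrium, so every feasible start
converges to the unique equilibrium.  Both quantities are exposed
(`lyapunov_value`, `lyapunov_derivative`) and recorded along trajectories.

**Inverse design.**  Rearranging L(x) = 0 yields S·cX − T·cY = U with
S = x[kx + K(cA−x)] and T = Kx(cA−x), both positive on (0, cA), so for a
desired free level one total can always be solved from the other;
infeasible requests (a fixed total that would force the other negative)
raise an error.

## Numerical choices

* **Root finding**: bracketed Brent iteration on (0, cA) with absolute
  tolerance 1e-12·cA; the guaranteed sign change makes this robust, and
  closed-form cubic formulas are avoided for stability.  The degenerate
  k = K case (all the worked scenarios) is a quadratic, solved by the
  numerically stable quadratic formula; cX = 0 short-circuits to x = cA.
* **Quadratic roots** elsewhere (the simple model) use the
  product-of-roots form when the linear coefficient is positive, avoiding
  cancellation.
* **Integration**: explicit forward Euler at fixed dt (default 0.001, the
  value the reference scenarios used) — chosen deliberately so scenario
  outputs match the original discretisation, not a black-box adaptive
  solver.  The RHS computes each reaction flux once, so the conserved
  totals are exact at the level of the update and drift only by rounding
  (asserted ≤ ~1e-9 per unit time in tests).
* **Nonnegativity**: the continuous system provably stays nonnegative, so
  the integrator clips only rounding-scale negatives (|v| < 1e-12) and
  aborts on anything larger — a real negative indicates a step size too
  large for the rates, not physics.  Jump noise and drift removal clip
  free A at zero (a removal can only take what is present).
* **Divergence**: self-replication runs are expected to escape; a run is
  labelled exploded once [A] > 10³ × initial cA or turns non-finite, stops
  cleanly and records the step (this is a result, not an error).
* **Reproducibility**: every stochastic component takes a single integer
  seed (numpy Generator); trajectories and censuses store it, and run
  files echo the effective parameters in their metadata header.

## Scenario forcings

* **Jump noise**: with probability 0.002 per step, [A] += U(−0.075, 0.075)
  (the published disturbance).  After a jump δ the relaxed equilibrium
  shifts by ≈ δ/β, which the tests verify to first order.
* **Drift ("noise function")**: the second reference scenario perturbs
  [A] with an unspecified monotone noise function; it is implemented here
  as the minimal such forcing, a constant signed rate s added to d[A]/dt
  ("falling" s < 0, "rising" s > 0).  Only the ordering claim — more
  inhibitor, smaller deviation — is treated as reproducible.
* **Self-replication**: d[A]/dt gains kRR[A]² − dR[A] (2A → 3A plus
  first-order decay).  Without inhibitors the level escapes in finite
  time; with the designed pair the escape is delayed by a large factor
  (≈ 30× with the published parameters) but not prevented.

## The spatial agent model

A continuous 2D torus (wrap-around avoids edge artefacts) carries
individual molecules: replicases, parasites, inhibitors, anti-inhibitors
and the two complex types.  Per step, in fixed order: diffusion → decay →
replication → parasite folding → inhibition chemistry.  Diffusion adds a
per-axis Gaussian displacement with variance 2·D·dt (D′ for complexes).
Two molecules can react when closer than twice the agent radius.
Replication requires a free replicase within range of the template,
succeeds with affinity aR (replicase template) or aP (parasite template)
times the global replication constant, is vetoed when the template has
≥ Nmax RNA neighbours, and replicase offspring mutate into parasites with
probability δ.  Binding and unbinding events fire with the Poisson-process
probability 1 − e^(−k·Δt); dissociations are processed before
associations so every complex exists for at least one full step.
Inhibitors and anti-inhibitors never decay: their totals are
integer-conserved, which the tests assert step by step.

The base agent model is only sketched in the source material, so several
semantics had to be fixed here; they were chosen so that the model
exhibits the documented phenomenology and are called out explicitly:

* **Folding** is a reversible conformational toggle (probability lP per
  step in each direction — one parameter, symmetric).  A folded parasite
  is protected from decay but can be neither copied nor bound.  This is
  the classic template-versus-stability trade-off, and it is what makes
  parasites fitter than replicases (effective mortality ≈ d/2 versus d):
  with irreversible, unprotected folding parasites are strictly less fit
  and the documented parasite takeover cannot occur.
* **Bound targets decay** at the normal rate d, releasing their inhibitor
  (a complex does not immortalise its target).  This is what gives
  inhibition its leverage: sequestration converts productive time into
  decay-only time.  If bound targets were protected, binding would scale
  parasite births and deaths by the same factor and could never reverse
  parasite growth.
* **Replication parallelism**: per step each template is copied at most
  once and each replicase copies at most once, but a replicase can copy
  and be copied in the same step.  Requiring a replicase to spend its
  step on one role makes the replicase population exactly marginal
  (birth ≈ death) at the reference density and extinction becomes
  drift-driven rather than parasite-driven.
* Offspring are placed uniformly within the interaction radius of the
  template; initial placement is uniform; event matching (which inhibitor
  binds which target) is greedy in random order with a uniformly random
  partner choice, which keeps runs seed-reproducible.
* Replicase extinction is terminal (parasites cannot copy anything), so
  runs stop at the extinction step by default.

**Emergent behaviour.**  At the reference parameter set the replicases
bloom, parasites overtake them within a few hundred steps and the whole
population collapses.  Dosing the arena with inhibitor/anti-inhibitor
pairs that bind parasites (only_P) rescues the system, with survival
frequency rising monotonically in the dose; binding replicases instead
(only_R) fails at every dose that rescues only_P — the replicase-side
strategy needs strictly more inhibitor, the ordering the source study
reports.  At this package's scale replicase-side control is strictly
harmful (sequestered replicases decay without working), so its own rescue
threshold, if any, lies beyond the tested range.

**Scale.**  The statistical tests and examples run at 1/16 of the
reference arena area with all populations scaled by the same factor:
densities, interaction radii and per-step probabilities are unchanged, so
the local dynamics are identical and only demographic noise grows.  At
that scale uncontrolled extinction lands near step 270, and a 600-step
horizon cleanly separates doomed from rescued runs; the only_P
dose-response transition sits near 60–90 inhibitor pairs (the scaled
equivalent of ~1000–1500 at full scale — rescue in this implementation is
cheaper than in the source study, whose thresholds depend on base-model
semantics not restated there).  Survival frequencies over 10 seeds carry
binomial noise of roughly one seed, which the monotonicity test allows
for explicitly.

## What the synthetic scenarios do and do not show

All inputs are parameter sets; there is no external data.  The
deterministic scenarios exercise the exact published parameter tables, so
agreement there validates algebra and integration, not biology.  The
agent model is a caricature: no sequences, no membranes, no energy
budget, a single arena scale, and interpretation choices documented
above.  Passing tests show that the control motif behaves as analysed
within this model family — buffering, delay of autocatalytic escape,
parasite-side dosing beating replicase-side dosing — not that these
mechanisms operated in any real primordial system.

## Known limitations

* Forward Euler is first-order; the package intentionally mirrors the
  reference discretisation rather than offering adaptive integration.
* The drift forcing is an interpretation of an unspecified noise
  function; only orderings, not curves, should be compared.
* Agent-model thresholds (inhibitor counts at which rescue occurs) are
  implementation-specific; only qualitative orderings are meaningful.
* The greedy event matching resolves contention in random order rather
  than sampling the exact joint distribution of simultaneous reactions;
  at the densities used, multi-way contention is rare.
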