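# Methods

## Model

The drug-free channel is a continuous-time Markov chain over eight
conformations — closed C3, C2, C1; open O; fast- and slow-inactivated IF, IS;
closed-inactivated IC3, IC2 — connected by ten reversible transitions
(activation/deactivation along each row, closed-state inactivation/recovery
verticals, open-state fast inactivation O↔IF, and slow inactivation O↔IS).
Occupancies evolve under the master equation dP/dt = Q(V)·P with the
**columns-as-source** convention: Q[j, i] is the rate from state i to state j,
so every column of Q sums to zero and probability is conserved exactly.

### Rate parameterization

Twelve voltage-dependent rates derive from 16 strictly positive free
parameters:

| rate | form | free parameters |
| --- | --- | --- |
| α11 | 1/(a11_v1·e^(−V/a11_v2)) | a11_v1 (ms), a11_v2 (mV) |
| α12, α13 | a12·α11, a13·α11 | a12, a13 (–) |
| β11 | 1/(b11_v1·e^(V/b11_v2)) | b11_v1 (ms), b11_v2 (mV) |
| β12, β13 | b12·β11, b13·β11 | b12, b13 (–) |
| α3 | a3_v1·e^(−V/a3_v2) | a3_v1 (ms⁻¹), a3_v2 (mV) |
| β3 | b3_v1·e^(V/b3_v2) | b3_v1 (ms⁻¹), b3_v2 (mV) |
| α2 | a2_v1·e^(V/a2_v2) | a2_v1 (ms⁻¹), a2_v2 (mV) |
| αx, βx | ax·α2, bx·α3 | ax, bx (–) |
| β2 | α13·α2·α3/(β13·β3) | *(constrained)* |

β2 is always derived, never optimized: it closes the single nontrivial loop
(C1–O–IF) of the scheme so detailed balance holds by construction rather than
by penalty. The two lattice squares (IC3–IC2–C2–C3 and IC2–IF–C1–C2) balance
identically because their opposite sides share rate labels. Exponentials are
evaluated in log space with a cap at e⁷⁰⁰ so that extreme voltages explored by
the optimizer degrade smoothly instead of overflowing.

### Drug-bound extension

A weak base partitions between protonated (charged) and neutral forms by
Henderson–Hasselbalch, f⁺ = 1/(1+10^(pH−pKa)); the two species bind
independently, each with its own mirror copy of the gating scheme (prefixes D
and N). Association is diffusion-limited, kon = [drug]·D, and dissociation
koff = Kd·D, with the charged open-state affinity following Eyring voltage
dependence Kd(V) = Kd0·e^(−d·V·F/(R·T)) (d the fraction of the membrane field
sensed at the site; F = 96485.3415 C/mol, R = 8314.472 mJ/(mol·K) so the
exponent is dimensionless with V in mV).

Charge-state access rules: the charged species binds only the open state
(Kd(V)) and the closed states (Kd evaluated at a fixed reference potential,
default −100 mV — the instantaneous-V alternative is configurable); its bound
branch includes a trapped inactivated state DIT entered from the drug-bound
open state. The neutral species reaches every conformation: closed and open
states with fixed affinities, inactivated states through the pair
ki_on/ki_off. ki_on is a second-order association constant (M⁻¹ms⁻¹, applied
as [neutral]·ki_on) and ki_off a first-order dissociation rate (ms⁻¹); both
are free. Treating ki_on as second-order keeps the zero-concentration limit
exact (all kon vanish, the extended model reproduces the drug-free model to
<1e−8 on every readout).

Drug-bound gating rates are scalar multiples of the drug-free rates. The main
text of the source literature names the 8 charged (αx1, βx1, α13c, α22, β33,
α33, α44, β44) and 8 neutral (αx2, α13n, α_22, β_33, α_44, β_44, ki_on,
ki_off) free quantities but not their exact edge assignment, so the package
ships a documented default map (data, overridable via
`ExtendedScheme.edge_map`):

* charged: mirror horizontals unscaled; verticals α33·α3 (up) / β33·β3 (down);
  DC1→DO = α13c·α13 and DO→DIF = α22·α2 with both reverses derived;
  DO↔DIS = αx1·αx / βx1·βx; trapping DO↔DIT = α44·α2 / β44·β2.
* neutral: because every neutral mirror state also carries a binding edge,
  assigning both directions of a mirror gating edge would over-constrain the
  binding squares; exactly one direction per edge is therefore free and every
  reverse is derived. Assignments: NC1→NO = α13n·α13, NO→NIF = α_22·α2,
  NO→NIS = αx2·αx, closed-row inactivation NC3→NIC3 = NC2→NIC2 = β_33·β3,
  NC1→NIF = β_44·β3, closed-inactivated-row horizontals scaled by α_44,
  closed-row horizontals unscaled.

**Cycle closure.** Reversibility is enforced generically: edges with both
directions assigned define log-potential differences between their endpoint
states; a spanning tree of that subgraph fixes the potentials, every
remaining both-assigned chord is checked for consistency (a contradiction
raises an over-constrained-cycle error), and each half-assigned edge receives
its reverse from the potential difference, making its fundamental cycle's
product ratio exactly one. The operation is idempotent and leaves the
extended scheme with every independent cycle balanced to <1e−10 in log space.

## Simulation

Protocols are piecewise-constant voltage commands, so each segment's solution
is exactly p(t) = e^(Qt)·p0. Segments are propagated by `scipy.linalg.expm`;
recorded segments use the eigendecomposition of Q (channel schemes are
reversible, hence real spectra; a conditioning check falls back to repeated
matrix exponentials). Scalar readouts never come off the sampling grid: the
grid only brackets the feature, after which the peak time is the root of the
analytic derivative dO/dt = (Q·p(t))_O (Brent, xtol 1e−13) and
time-to-half-decay is found by monotone bisection/Brent on the analytic
segment solution. Halving the sampling step therefore changes readouts by
less than 1e−6. Tau50 is measured from the (refined) peak time, not from
pulse onset.

"Current" readouts use the open-state occupancy O(t); all fitted quantities
(availability, activation, recovery and block fractions, Tau50, mean open
time) are normalized or time-based and thus independent of the conductance
and driving force, which the package does not model. Mean open time is
analytic — the reciprocal of the total exit rate from O,
1/(β13+α2+αx) — with a stochastic competing-clocks simulation retained only
as a test oracle.

Initial conditions are the stationary distribution at the holding potential
(the exact limit of holding until the occupancy change vanishes). Protocols
on drug-extended models default to drug-equilibrated rest; a
`drug_start="drug_free"` option starts from the drug-free equilibrium with
empty bound states instead.

## Protocol battery and defaults

The inset-level numbers of the classic protocols are not printed in the
source text, so the bundled YAML uses the stated anchors (recovery from
inactivation at −100 mV, mean open time at −30 mV, 10 Hz use-dependent-block
trains at 10 and 100 μM, time-to-50%-decay) and declares the rest as package
defaults: holding −100 mV; 500 ms conditioning prepulses and a −20 mV/25 ms
test pulse for availability (9 prepulse voltages); activation test steps
−60…+10 mV; recovery intervals 1–10⁴ ms; 20-pulse 25 Hz conditioning trains
for drug-free recovery; 30-pulse trains for the drug protocols;
frequency-dependent block at 2–20 Hz. All of these are data, editable without
code changes.

The synthetic-data generator simulates this battery from a frozen generating
parameter set chosen to give physiological wild-type kinetics (availability
midpoint ≈ −85 mV, activation completing near +10 mV, sub-millisecond mean
open time at −30 mV, α3(−20 mV)·ax ≈ the reported slow-inactivation scale,
bx = α3/45) and adds optional i.i.d. Gaussian noise on the normalized
readouts. What passing recovery tests show is therefore *identifiability of
the model under its own protocols*, not agreement with any laboratory
dataset: real data add driving-force and series-resistance effects,
correlated sweep-to-sweep variability and rundown that the generator does not
emulate.

## Optimization

Each protocol contributes SSE/n_points, so protocols weigh equally per unit
misfit regardless of how densely they sample (a 9-point availability curve
vs. a single mean open time). Per-protocol costs are independent and may be
evaluated concurrently (joblib threads); the combination is ordered by
dataset registration, making the total bitwise identical for any worker
count. A failing simulation contributes an infinite sentinel instead of an
exception so pathological parameter regions do not abort the search.

Minimization is Nelder–Mead on a smooth bounded transform (log for one-sided
positivity, sin² for boxes — the classic bounded-simplex construction, chosen
over projection because projected simplices stall on faces). Convergence
requires the simplex cost spread *and* parameter spread to fall below their
tolerances simultaneously (defaults 0.01/0.01); iteration counts are simplex
iterations. The best-so-far cost is logged per iteration. Restarting the
simplex from the incumbent after convergence (fresh simplex, same point) is
the recommended way to polish high-dimensional fits; ±10% multiplicative
uniform restarts (`restart_perturbed`) help escape shallow local minima.

Sequential scheduling optimizes cumulative protocol groups in 100-iteration
blocks (group 1, then 1+2, …), for one ordering or the full factorial set
(4! = 24), then continues the best ordering to convergence. The two-stage
drug fit first optimizes the 8 neutral scalars against neutral-analog
datasets (charged fraction forced to 0, emulating a fully neutral
derivative), freezes them, and then fits the 8 charged scalars over the
five-protocol drug battery.

## Robustness study

Starting from parameters defined as the true optimum (zero cost on noise-free
fixtures), each parameter is multiplied by an independent uniform factor in
[1−p, 1+p] (p = 5, 10, 25% — uniform chosen as the most direct reading of
"± p%"; the distribution is configurable), the fit is restarted, and
recovered/true ratios are aggregated as per-parameter means and normalized
SDs over 3 runs per level. The study defaults to a reduced budget of 500
simplex iterations per run so the full 9-run suite completes at desk scale;
the spread (normalized SD averaged over parameters) is non-decreasing in the
perturbation level on noise-free data.

## Numerical choices

* Stationary distributions: SVD nullity check (uniqueness), then the
  augmented least-squares system [Q; 1ᵀ]π = [0; 1], which is better
  conditioned than reading the SVD null vector when rates span many orders of
  magnitude; entries below −1e−8 (relative) are an error, smaller negatives
  are clipped.
* Conservation checks are relative to the largest rate magnitude.
* Exponential fits (y = C1 − A1·e^(−t/τ1) − A2·e^(−t/τ2)) use bounded
  least squares with τ ≥ 0 and report components ordered τ1 ≤ τ2; the
  recovery-rate regression log(1/τ1) ~ V flags a flat slope (b → ∞) as
  degenerate. The proportionality constant linking α3 to 1/τ1 defaults to 1
  and is configurable.
* All randomness flows from explicit seeds (numpy `default_rng`); run
  manifests (seed, options, input hashes) accompany every CLI output.

## Known limitations

* The drug-bound edge→scalar map is a defensible default, not a measured
  topology; alternative maps change which scalars are identifiable.
* No conductance model: absolute current amplitudes, and protocols that
  depend on driving force (e.g. reversal-potential effects), are out of
  scope, as are ramp/sinusoidal commands and temperature scaling of rates.
* Several parameters are only weakly constrained by the bundled battery
  (notably the a3_v1/b3_v1 pair, which trades off along a ridge that leaves
  all fitted curves nearly unchanged); the robustness study quantifies this
  rather than hiding it.
* Identifiability is assessed empirically (perturb-and-refit, sensitivity
  thresholds), not by formal structural-identifiability analysis.
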