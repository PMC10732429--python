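# Model and methods

`merkelsim` simulates a single Merkel cell — the epidermal mechanosensory
cell that drives slowly-adapting type-1 (SA1) touch afferents — as a
deterministic system of 28 coupled ordinary differential equations. The
state comprises the cytosolic mole numbers of Na⁺, K⁺, Cl⁻ and Ca²⁺, the
membrane potential V_m, ten Hodgkin–Huxley gating variables, the four
Piezo2 state-machine variables, ER and mitochondrial Ca²⁺ contents, IP₃
and its precursor, the two IP₃-receptor gates, the cell volume, the
unstressed reference surface S_ref, and the vesicle count n_ve. A fixed
amount of impermeant intracellular anion A⁻ (amount and mean valence
solved at initialisation) closes the osmotic and charge budgets.

## Plasma membrane

Channels follow the Hodgkin–Huxley form dx/dt = (x∞(V_m) − x)/τ_x(V_m)
with channel-specific steady-state and time-constant fits:

* **Kv1.4** — J = −g·m⁴(0.7·h_fast + 0.3·h_slow)(V_m − E_K)/F; fast
  activation, double-exponential inactivation.
* **Kv4.2** — J = −g·m·h(V_m − E_K)/F.
* **BKCa** — J = −g·n(V_m − E_K)/F; the half-activation voltage
  V_half = −43.3·pCa − 110 mV with pCa = log₁₀(C_Ca/1 mM) shifts left as
  cytosolic Ca²⁺ rises, coupling the Ca²⁺ and K⁺ systems.
* **KDR** — slow delayed rectifier, J = −g·n(V_m − E_K)/F.
* **Cav1.2** — L-type Ca²⁺ channel, J = −g·m·h·hCa(V_m − E_Ca)/F with the
  algebraic Ca-dependent inactivation hCa = 1/(1+(C_Ca/1 µM)⁴).
* **Cav2.1** — P/Q-type, non-inactivating, J = −g·n(V_m − E_Ca)/F.
* Ohmic leaks for all four ions; Nernst potentials from the instantaneous
  concentrations.

Transporters: the Na⁺/K⁺ pump (rate saturable in internal Na⁺ and
inhibited by internal K⁺, 3 Na⁺ out / 2 K⁺ in / +1 charge out per cycle);
NKCC1 (mass-action product difference, 1 Na⁺:1 K⁺:2 Cl⁻, electroneutral);
KCC2 (see below); PMCA (Hill-2 Ca²⁺ extrusion); and the electrogenic
3 Na⁺:1 Ca²⁺ exchanger NCX with voltage partition η = 0.1 and saturation
factor k_sat = 0.35.

**Sign convention.** Every membrane flux is a molar flux density
(mol m⁻² s⁻¹) positive *into* the cytosol. For cations this equals the
conventional −g·p_open·(V_m − E)/F; the inward Cl⁻ flux has the opposite
sign of the same ohmic current. The V_m equation weighs each flux by its
carried charge (×2 for Ca²⁺ pathways, −1 for inward Cl⁻, −1 per Na/K-pump
cycle, −1 per NCX cycle, −2 per PMCA cycle). A positive NCX rate here
means reverse mode (Ca²⁺ in, 3 Na⁺ out); at rest the exchanger runs
forward and extrudes Ca²⁺. This is the only sign assignment that makes
the mass balances, the charge balance and the stated physiological
directions mutually consistent, and it is verified by an independent
re-summation test.

**KCC2 driving force.** The published KCC2 expression is not a well-formed
formula and its printed units (mol cm⁻² ms⁻¹) do not match a raw
product-difference form. We use the dimensionally consistent normalised
product difference J = P·(C_K C_Cl / (C_K,out C_Cl,out) − 1): zero at
thermodynamic equilibrium, extruding K⁺ + Cl⁻ when the internal product is
larger, and of sensible magnitude with the printed rate constant.

## Piezo2

Piezo2 is gated by cortex stress σ, not voltage, through a four-variable
state machine: closed C, open O, short-inactivated In (C + O + In = 1) and
an independent slow availability h_slow; only g·O·h_slow conducts, and the
whole current is booked as Ca²⁺ (divalent). Loading kinetics move C → O →
In with stress-dependent time constants (0.5–2 ms, 2.5–8 ms); unloading
returns In → C while O is untouched; h_slow relaxes with τ up to 150 ms.
All steady-state curves share the midpoint stress 1450 Pa. Under a
sustained load the open fraction adapts fully to zero — the model's
explanation for why sustained mechanotransduction relies on intracellular
Ca²⁺ stores rather than a sustained Piezo2 current.

The loading/unloading regime is an explicit protocol-driven flag (loading
while a stimulus is applied or held, unloading from release), because the
kinetics themselves contain no stress criterion. Two caveats are
documented rather than patched: (i) each regime is positivity-preserving
only in its intended stress range (loading with C ≥ C∞(σ), unloading at
low σ); when slow osmotic drifts during a purely electrical stimulus let
σ dip below its quasi-steady value, O can drift a few 10⁻³ below zero.
The conducting fraction is clamped at zero consistently in the right-hand
side and in the flux reports, and C + O + In = 1 is preserved exactly.
(ii) The exact-relaxation kernel (`piezo2.advance`) is the unit-testable
closed form of the same equations at constant σ.

## Intracellular stores

ER: SERCA uptake (Hill-2, K = 0.1 µM); RyR Ca²⁺-induced Ca²⁺ release with
a hard threshold at 0.3 µM cytosolic Ca²⁺ (the printed rate law is
discontinuous there; we bridge the jump over a 4·10⁻⁵ µM band with a
smoothstep so the stiff solver sees a C¹ flux — far below any physical
resolution); and an IP₃-receptor flux (P_leak + P_IP3·Hill₃(IP₃)·m·h)
·(C_ER − C_Ca) with a bell-shaped Ca²⁺ dependence through the slow gates
m (activating, midpoint 0.4 µM, τ = 10 s) and h (inhibiting, midpoint
0.6 µM, τ = 20 s). IP₃ is produced from a self-limiting precursor pool at
a Ca²⁺-saturable rate and decays first order. Mitochondria: MCU uptake
(Hill-2.3, K = 0.6 µM) and MNCX release (Michaelis, K = 1 µM), damped by
the membrane buffer factor 1/(1+β), β = 0.3.

Three printed-equation inconsistencies are corrected by default, each with
a config switch restoring the literal form: the IP₃R inhibition gate
relaxes as (h∞ − h)/τ_h (the printed difference uses m, which would let h
leave [0,1]; switch `literal_ip3r_h_equation`); the IP₃-production
saturation uses K² in both places it appears (`literal_ip3_production`);
and vesicle synthesis decreases with pool size as the accompanying text
states, not increases as the printed sigmoid sign would have it
(`literal_vesicle_synthesis`).

**A consequence of the published rate constants.** With the tabulated
values the ER release-path conductances (P_leak = 0.7·10⁻³ cm/ms,
P_RYR = 8.5 cm/ms) exceed the SERCA rate (0.7·10⁻¹⁷ mol cm⁻² ms⁻¹) by
many orders of magnitude, so the resting ER–cytosol Ca²⁺ gradient is
≈10⁻⁵ µM and the ER tracks the cytosol with a ~0.1 ms time constant: it
behaves as a fast passive buffer volume, not as a dischargeable store.
Blocking the ER pathways therefore *raises* the peak of a stimulated Ca²⁺
transient slightly (the buffer is removed) instead of lowering it. The
sustained, tens-of-seconds Ca²⁺ tail in this implementation is carried by
the mitochondrial compartment (slow MNCX release of accumulated Ca²⁺)
together with PMCA/NCX clearance. We deliberately did not re-scale any
store constant to manufacture a dischargeable ER; all values are used as
tabulated.

## Mechanics and volume

Cell volume obeys dV/dt = S·J_water, J_water = −α(ΔP − ΔΠ), with the
van 't Hoff osmotic difference ΔΠ = RT(ΣC_in − ΣC_out) (the internal sum
includes A⁻, the external sum any impermeant mannitol) and the Laplace
pressure ΔP = 2 h_c σ / r of a thin elastic cortex, σ = K/2·(S/S_ref − 1)
− σ_a with K = 6 kPa and active stress σ_a = −100 Pa. Osmotic equilibrium
is stiff: a fractional volume error of 10⁻⁴ produces a ~13 Pa pressure
imbalance, so volume relaxes on a ~0.2 ms time scale.

Indentation to depth d maps the resting sphere (radius r_ini = 5 µm, a
configurable default chosen so that the deepest published indentations,
7.9 µm, remain below the cell diameter) onto a volume-conserving cylinder
of height H = 2·r_ini − d; its total surface (two discs plus wall) drives
σ, and the cylinder radius enters the Laplace relation. This reconstruction
has two knowingly accepted artefacts: the surface (hence σ) jumps ~15% at
first contact, and is slightly non-monotone in d below ~2 µm; above 3 µm —
the protocol range — the surface grows strictly with depth. The geometry
function is isolated behind an interface so an alternative shape map can
be swapped in.

## Vesicle cycle

Exocytosis consumes vesicles at k_exo·sigmoid((C_Ca − 0.2 µM)/0.01 µM)
·n_ve; synthesis refills the pool with a sigmoid that halves at 500
vesicles; endocytosis retrieves membrane at k_endo·sigmoid(−(σ − 1 kPa)/
15 Pa). Each fused (retrieved) vesicle adds (removes) 4πr_ve² of
unstressed reference surface, which couples the vesicle cycle back into
the mechanics: at rest, endocytosis–exocytosis balance pins the resting
cortex stress near 1.1–1.3 kPa (S_ref shrinks below the geometric
surface until retrieval is throttled). This emergent pre-tension is what
places the resting cell within reach of the Piezo2 activation range, so
that both indentation and hypotonic swelling open the channel. The
exocytosis rate is exported in every trace as the neurotransmitter-release
proxy; the "exocytosis duration" summary is the time the rate exceeds a
configurable multiple (default 2×) of its pre-stimulus baseline.

## Stimulus protocols

Rectangular current injection (the pipette current is additionally booked
as a K⁺ source in the mass balance — a 60 s, 114.1 pA injection carries
more charge than the cell's entire resting K⁺ content, which a whole-cell
pipette physically replenishes; without this the cytosol would drain below
zero); high-K⁺ bath swap (±130 mM K⁺/Na⁺); hypotonic shock (removal of
30 mM external mannitol from a mannitol-supplemented baseline); and
ramp-and-hold compression (default 1 µm/ms) with protocol-driven Piezo2
phase. Protocol onsets, ramp ends and releases are solver restart points.

## Numerics

* Internal units are strictly SI; config loaders convert the conventional
  table units (mS/cm², mol cm⁻² ms⁻¹, cm/ms, µM, ms, µm) at the boundary
  and nowhere else.
* Integration: SciPy BDF with rtol 10⁻⁶ and per-variable absolute
  tolerances scaled from resting magnitudes. All sigmoids are evaluated
  in overflow-safe form; solver trial points outside the physical domain
  are clamped (gates to [0,1], concentrations to a positive floor and a
  far-unphysical ceiling) inside the right-hand side only.
* The resting state is found by long stiff relaxation (600 s, escalating
  when needed — near the fixed point the solver's steps grow, so extra
  simulated time is nearly free), an algebraic pre-solve of the two
  ultra-slow variables (n_ve and S_ref have intrinsic time constants of
  hours), and a damped-Newton polish with an explicit finite-difference
  Jacobian on the remaining 26 variables. The Jacobian is rank-deficient
  by one because the charge-weighted ion balances and the V_m equation
  are linearly dependent (total charge is conserved); a least-squares
  solve handles this, and the Piezo2 In fraction — which has no feedback
  under loading kinetics — is pinned by the simplex constraint instead of
  its derivative. Convergence requires the per-second scaled derivative
  max-norm < 10⁻⁸, and the resting V_m must fall in a configurable sanity
  band (default −80…−40 mV).
* The fixed-step verification oracle (classical RK4 at dt = 10⁻³ ms over
  a 200 ms window) is run on a passive negative-pulse response, where the
  fastest active mode (volume relaxation, ~6·10³ s⁻¹) is within the RK4
  stability limit; windows in which the RyR threshold is crossed activate
  an ER–cytosol exchange mode of ~10⁸ s⁻¹ that no explicit method at this
  step size can integrate.

## Reference experiments

The scenario registry mirrors the published validation and sweep panels
with their exact caption values: passive negative pulses and peaked
positive pulses (both electrophysiology presets), the high-K⁺ swap with
and without ER block, hypotonic shock, conductance/pump sweeps for both
the 200 ms membrane-potential window and the 60 s Ca²⁺-transient window,
and 100 ms/20 s compression series over depths 3–7 µm including the
Piezo2-knockout control. Sweep runs relax their own resting state per
grid point (resting levels depend on pump parameters). Pulse durations
for panels that do not print them are fixed at 200 ms.

## What the simulations do and do not show

All experiments are self-generated simulations of a single, spatially
uniform cell; there is no external data and no fitting. Passing tests
demonstrate internal consistency (conservation laws, gating identities,
solver accuracy) and that the stated qualitative response shapes emerge
from the tabulated constants — not that a real Merkel cell behaves
quantitatively like the model. Known gaps inherited from the model
design: no spatial Ca²⁺ diffusion or waves, no Na⁺/K⁺ permeation through
Piezo2, no neurotransmitter recycling, no afferent coupling, and the
single-compartment ER behaviour discussed above.
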