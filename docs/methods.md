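# Methods

## The model

A protein monomer is in one of two conformations: a soluble, coil-like state
**C** and a β-strand state **B** adopted on the filament. A filament is a
contiguous β-core of `n_β` B monomers terminated, at its single growing tip,
by a *cap* of `k` C monomers. Seven rate constants drive the dynamics (time
in hours, concentration in μM, length in monomers; 2 monomers = 1 nm of
axial rise in a cross-β stack):

| symbol | event | note |
|---|---|---|
| `k_p_cc · c` | C binds a terminal C | cap ≥ 1 |
| `k_d_cc` | terminal C unbinds from C | cap ≥ 2 |
| `k_p_bc · c` | C binds the bare B end | cap = 0 |
| `k_d_bc` | the lone cap C unbinds from B | cap = 1 |
| `s_cb` | leftmost cap C switches to B | cap ≥ 1; cap−1, core+1 |
| `s_bc` | rightmost core B switches to C | core ≥ 2; taken as 0 in theory |
| `k_d_bb` | terminal B unbinds from B | taken as 0: B–B contacts are effectively irreversible |

Switching is sequential: C→B acts on the leftmost cap monomer (adjacent to
the core), B→C on the rightmost core monomer. A lone B in solution is
unstable, so seeded simulations never let the core drop below one monomer.

## Closed-form steady state

With `s_bc = k_d_bb = 0` the cap size is a birth–death chain. Two
dimensionless ratios control everything:

    r(c) = k_p_cc·c / (k_d_cc + s_cb)       cap-tail ratio
    a(c) = k_p_bc·c / (k_d_bc + s_cb)       empty-cap escape ratio

For `r < 1` (**regime 1**) the stationary cap distribution is

    P_0 = (1 − r) / (1 − r + a),   P_k = P_0 · a · r^(k−1)  (k ≥ 1),

`q = 1 − P_0 = a/(1 − r + a)` is the probability of finding at least one C
at the tip, and the elongation velocity assembled term by term,

    v_f = P_0·k_p_bc·c + q·k_p_cc·c − P_1·k_d_bc − (q − P_1)·k_d_cc,

collapses algebraically to `v_f = s_cb · q`: with a stationary cap, every
*permanent* length gain is a monomer locked in by a conformational switch,
so the β-front velocity `v_β = s_cb · q` equals `v_f` in regime 1 and both
are bounded by the switching rate. For `r ≥ 1` (**regime 2**) the cap grows
without bound, `v_f = k_p_cc·c − k_d_cc` (cap-driven, linear in
concentration) while `v_β = s_cb` exactly. The regimes meet at

    [C]** = (k_d_cc + s_cb) / k_p_cc,

where both branches equal the saturation velocity `s_cb` — the origin of the
concentration-independent elongation plateau that distinguishes
switching-stabilized filaments from, say, microtubules. `[C]*` (where q
reaches 1) and `[C]**` (where the regime-2 line crosses `s_cb`) are computed
by separate code paths and asserted equal; the term-by-term regime-1 flux,
the `s_cb·q` identity, a truncated-master-equation linear solve, a
time-integration of the forward equation, and Gillespie simulation all agree
on the same numbers, which is the package's guard against bookkeeping errors
in the boundary cases (k = 0, 1).

Numerics: the returned `P_k` vector is truncated where residual geometric
tail mass falls below 1e−12 (capped at 10^6 entries near criticality); the
oracle chain reflects at `kmax` and escalates `kmax` geometrically until the
stationary tail mass is < 1e−10; tiny negative flux residues (< 1e−9 of the
rate scale) from floating-point cancellation are clamped to zero.

## Force response and the operational stall force

Growth against a constant opposing load `F` rescales the four
polymerization/depolymerization constants Boltzmann-fashion:
`k_p → k_p·exp(−α·F·d/k_BT)`, `k_d → k_d·exp((1−α)·F·d/k_BT)` with `d` the
axial rise (0.5 nm) and `α ∈ [0,1]` the load-distribution factor. Switching
rates are untouched (switching moves no mass against the wall). The product
of the two factors is `exp(−F·d/k_BT)` for every `α` — an identity the tests
check to machine precision, since it is the sharpest guard against
transposing an exponent.

Because the β-core never depolymerizes, the loaded stationary velocity
`v(F) = s_cb·q(F)` is strictly positive at any finite force: `v(F) = 0` has
no finite root. What a force–velocity curve actually shows is a steep
collapse where the load pushes the tip across the regime boundary
(`r(F) = 1`) and the cap drains. `stall_force` therefore returns an
*operational* stall: the load at which velocity first falls below 5% of its
unloaded value (a detection threshold, configurable via `stall_fraction`),
located by doubling-bracket plus bisection to 1e−3 pN. At the Aβ preset's
reference concentration (150 μM) this crossing happens on the regime-2
branch, which does not involve `s_cb` at all — hence the stall force
(3.20 pN) is exactly invariant under changes of the switching rate. The
force–velocity profile is concave (flat, then collapsing) at saturated
regime-1 concentrations such as 90 μM; at regime-2 concentrations the
decline starts immediately. The Boltzmann decay scale `k_BT/d ≈ 8.2 pN`
means no parameter choice can confine both the concave plateau and a deep
collapse within a couple of pN.

## Kinetic phase diagram

With a critical (detectability) velocity `v_c` — default 0.5 μm/day ≈ 41.7
monomers/hr, roughly the shortest filament visible by light microscopy per
day — each `(s_cb, c)` point is labelled:
*no-aggregation* if `v_f < v_c`; *disordered* if `v_f ≥ v_c` but
`v_β < v_c`; *partially-ordered* if both exceed `v_c` and `v_f > 2·v_β`;
*ordered* otherwise. Since `v_f = v_β` in regime 1, disordered and
partially-ordered labels live entirely in regime 2. Boundary level sets
(`v_f = v_c`, `v_β = v_c`, `v_f = 2 v_β`) are exported per switching rate as
bisection roots along concentration.

## Simulation

The Gillespie kernels (numba-compiled) implement the exact event set above
under three setups: constant free-monomer concentration; mass-conserved
(instantaneous concentration `c_0 · n_free/n_free(0)`, polymerization and
depolymerization moving monomers between pool and filament with exact
integer bookkeeping); and constant-concentration with fragmentation, where
each B–B bond breaks at `k_frag` per hour, the fragment keeping the original
cap retains the parent's identity and the bare-B fragment becomes a new
lineage-tracked seed (cap-internal bonds can be enabled, in which case an
all-C fragment dissolves back into the pool). `k_frag = 0` delegates to the
plain constant-concentration simulator, making the zero-rate identity exact
by construction. Ensembles derive run seeds as `base_seed + run_index` and
are bit-reproducible; lengths are step functions, so grid sampling carries
the last value forward.

## Estimators

* **Steady velocity**: OLS slope of length vs time after a burn-in; for
  ensembles, the mean of per-run slopes with a between-run SE (event-time
  samples are autocorrelated, so within-run residual SEs understate error).
* **Initial velocity** (mass-conserved): `(L(t10) − L(0))/t10`, `t10` the
  first time length reaches 10% of the run's maximum.
* **Heterogeneity**: population σ of length across realizations; its peak
  time τ is read off a 5-point centred moving average. Under depletion σ
  rises, peaks near the growth knee and decays as all filaments approach the
  pool ceiling; τ is inversely proportional to `s_cb` when growth is
  switching-limited throughout, which holds when `k_d_cc` and `k_d_bc`
  dominate the swept `s_cb` values so that `q` barely moves across the
  sweep. The τ-sweep scales each ensemble's horizon as
  `3 · n_total / v(c_0)` so slow switchers get proportionally longer
  windows. A σ/⟨L⟩ convenience column is included; it decays monotonically
  at long times.
* **Stop-and-go**: the first 60 h are cut into 10-min windows; a window
  whose forward length difference is below 2 nm/min (240 monomers/hr) is a
  stop, adjacent same-phase windows merge, so segments tile the interval
  exactly. Interior (uncensored) dwells are pooled; each phase gets a
  shifted-exponential MLE — the shift of half a window is the standard
  dead-time/lattice correction for windowed dwell records — with a
  one-sample KS statistic, plus a two-sample KS for go/stop similarity.
  Window size trades velocity resolution against dwell quantization; with
  the default threshold, means below ~8 windows are dominated by lattice
  effects.

## Presets

Only a few anchors of the published parameter sets are printed as numbers:
the Aβ saturation velocity (15 nm/hr × 2 monomers/nm = 30 monomers/hr), the
2 monomers/nm rise, the 0.5 μm/day critical velocity and the 2 nm/min stop
threshold. The presets are therefore calibrations against the documented
constraints rather than transcriptions, fixed once:

* `fig3_abeta_fit` — `k_p_cc = 30 /μM/hr`, `k_d_cc = 2970 /hr` (weak,
  sub-second C–C contacts), `k_p_bc = 3 /μM/hr`, `k_d_bc = 30 /hr` (stable
  B–C contact), `s_cb = 30 /hr` (pinned by the saturation velocity), giving
  `[C]** = 100 μM`, a smoothly saturating concentration–velocity curve, a
  3.2 pN stall at the 150 μM reference concentration insensitive to `s_cb`,
  and a concave force–velocity profile in the saturated regime.
* `fig7_stop_go` — `k_p_cc = 100 /μM/hr`, `k_d_cc = 400 /hr`,
  `k_p_bc = 0.4 /μM/hr` (250× weaker B-end binding), `k_d_bc = 450 /hr`,
  `s_cb = 630 /hr` at 10 μM: the cap-tail ratio is 0.971 (top of regime 1),
  so growth alternates between multi-hour bare-tip waits (stops) and
  cap-excursion bursts at ≈600 monomers/hr (gos), with comparable numbers
  of stop and go segments.

## What the simulations do and do not emulate

The generator produces single, isolated filaments with one growing end,
perfectly monodisperse monomers, and (in mass-conserved mode) a well-mixed
pool with concentration proportional to free-monomer count. It does not
model primary or secondary nucleation, monomer diffusion or surface effects,
many-filament competition under constant concentration, or two-ended growth
— so passing tests validate the tip-cap kinetics, not whole-sample (ThT-type
sigmoidal) aggregation curves.

## Known limitations

* At exactly `[C]**` the cap walk is critical (birth = death): the
  finite-time KMC length velocity exceeds `s_cb` by a slowly decaying
  `O(t^{−1/2})` cap-growth transient. Saturation-velocity measurements are
  therefore made just inside the ceiling (0.98·`[C]**`), where they converge
  cleanly to the plateau.
* Go-phase dwell times are busy periods of a near-critical birth–death
  chain. Their law keeps a scale-free `t^{−3/2}` body under any parameter
  choice compatible with visible go phases, so at large sample sizes
  (n ≈ 500+) a KS test rejects a single exponential for the go phase — and,
  by shape, go/stop statistical identity — even though the empirical
  survival curve looks exponential by eye over the observed range. Stop
  phases are genuine memoryless waits and pass. See the stop-and-go
  acceptance test, which records this discrepancy rather than hiding it.
* `estimate_switching_rate` detects a plateau by comparing the slope of the
  last three points against 5% of the curve's maximum slope; curves with a
  steep final approach to the plateau can be flagged "still rising" and then
  yield only a lower bound.
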