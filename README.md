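# fibriltip

Kinetics of amyloid filament elongation with explicit conformational
switching: closed-form theory and exact stochastic simulation of a single
growing fibril tip.

## The problem

Amyloid fibrils — the cross-β assemblies behind Alzheimer's and Parkinson's
pathology as well as many functional protein polymers — grow by recruiting
soluble, coil-like monomers (**C**) that subsequently switch on the filament
into a β-strand conformation (**B**). The filament is a stable β-core topped
by a fluctuating cap of k unconverted C monomers at the tip. `fibriltip` is
for modellers and single-filament experimentalists who want the measurable
consequences of that two-state picture: concentration–velocity curves and
their saturation, force generation and stall, kinetic phase boundaries,
filament length heterogeneity, and intermittent (stop-and-go) growth.

## The model

Six rate constants act on the tip: C-on-C polymerization `k⁺_cc·[C]` and
depolymerization `k⁻_cc`, C-on-B binding `k⁺_bc·[C]` and unbinding `k⁻_bc`,
and sequential conformational switching at `s_cb` (leftmost cap C → B; the
reverse rate is negligible, and B–B contacts are effectively irreversible).
The cap size is then a birth–death chain with

    r = k⁺_cc[C] / (k⁻_cc + s_cb),    a = k⁺_bc[C] / (k⁻_bc + s_cb).

For r < 1 (regime 1) the cap is stationary, P₀ = (1−r)/(1−r+a),
Pₖ = P₀·a·r^(k−1), and the elongation velocity is the locking flux

    v_f = v_β = s_cb · q,        q = 1 − P₀,

bounded by the switching rate — hence a concentration-*independent*
velocity plateau at high [C], a signature of switching-stabilized
polymerization. For r ≥ 1 (regime 2) the cap grows without bound and
v_f = k⁺_cc[C] − k⁻_cc grows linearly while v_β = s_cb. Both branches equal
s_cb at the boundary [C]** = (k⁻_cc + s_cb)/k⁺_cc. An opposing load F
rescales the on/off constants by exp(−αFd/k_BT) and exp((1−α)Fd/k_BT)
(d = 0.5 nm per monomer). All closed forms are cross-checked against a
brute-force truncated master-equation solver and exact Gillespie simulation.

## Worked example

```python
from fibriltip import (get_preset, filament_velocity, saturation_velocity,
                       stall_force, Conditions)

p = get_preset("fig3_abeta_fit")          # Abeta elongation calibration
for c in (10, 50, 90, 110):
    pt = filament_velocity(p.rates, c)
    print(f"c={c:>3} uM  regime {pt.regime}  v_f = {pt.v_f:7.2f}  "
          f"v_beta = {pt.v_beta:6.2f} monomers/hr")
s, css = saturation_velocity(p.rates)
print(f"saturation: {s} monomers/hr at [C]** = {css} uM")
print(f"stall force at 150 uM: {stall_force(p.rates, 150.0, Conditions(conc=150.0)):.2f} pN")
```

prints

```
c= 10 uM  regime 1  v_f =   10.71  v_beta =  10.71 monomers/hr
c= 50 uM  regime 1  v_f =   25.00  v_beta =  25.00 monomers/hr
c= 90 uM  regime 1  v_f =   29.35  v_beta =  29.35 monomers/hr
c=110 uM  regime 2  v_f =  330.00  v_beta =  30.00 monomers/hr
saturation: 30.0 monomers/hr at [C]** = 100.0 uM
stall force at 150 uM: 3.20 pN
```

Below [C]** = 100 μM growth is switching-limited (filament and β-content
velocities coincide and saturate at s_cb = 30 monomers/hr = 15 nm/hr); above
it the filament elongates as a disordered C-polymer, 11× faster at 110 μM
while the β-front still advances at only 30 monomers/hr. The 3.2 pN
operational stall (velocity below 5% of unloaded) is the piconewton-scale
force a single growing fibril can work against.

The same operations are exposed as a CLI:

```
fibriltip velocity-curve --preset fig3_abeta_fit --out vc.tsv
fibriltip simulate --preset fig7_stop_go --seed 1 --t-end 60 --out traj.tsv
fibriltip stop-go  --preset fig7_stop_go --seed 1 --out dwells.json
fibriltip validate --seed 0        # closed form vs master equation panel
```

All outputs are TSV/JSON with the resolved parameters embedded in `#`
headers; every stochastic command is bit-reproducible from `--seed`.

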