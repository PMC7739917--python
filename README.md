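# vasclbm

A desk-scale lattice Boltzmann toolkit for **self-coupled arterial–venous
blood-flow simulation**.  Two solver instances — one for an arterial tree,
one for a venous tree — run in lockstep and exchange patch-averaged
boundary states through a mass-conserving 1:N coupling map that stands in
for the unresolved capillary bed between them.  The package is aimed at
computational-hemodynamics researchers who want to study, test or extend
the coupling strategy itself without a cluster: all geometries are
synthetic voxel fixtures generated in code, and every experiment runs in
minutes on one CPU core.

## The model

Each tree is a D3Q19 single-relaxation-time (BGK) lattice Boltzmann fluid
on a sparse voxel domain: rigid no-slip walls via halfway bounce-back,
Newtonian rheology, velocity inlets and pressure outlets realized as
equilibrium-completion closures, and body forces incorporated with the
second-order Guo scheme.  Validity is governed by the viscosity relation
ν = (1/3)(τ − 1/2)Δx²/Δt and the computational Mach number
Ma = 3 v_max Δt/Δx < 0.1, with τ preferred in (0.5, 1].

The coupling works on boundary *patches* (iolets).  Every arterial outlet
(subscript 0) heads a group of links to venous inlets i = 1…N, built by a
two-pass nearest-centroid assignment that guarantees every outlet is
coupled and every inlet is assigned.  Per link, the capillary bed is a
linear resistance: the pressure drop is proportional to flow rate times
path length, ΔP_i = k_i q_i L_i, with k_i ∝ 1/A_i.  Sampling
ΔP_i/P_0 ~ U(0.3, 0.7) and imposing mass conservation q_0 = Σ q_i yields
the velocity scale factors

    v_i / v_0 = (A_0 / A_i) · w_i / Σ_j w_j ,   w_i = ΔP_i A_i / L_i ,

which satisfy Σ_i (A_i/A_0)(v_i/v_0) = 1 exactly: the venous inflow
carries the whole arterial outflow.  During a run the instances alternate
**forward** exchanges (venous inlet velocity targets = factor × mean
arterial outlet velocity) and **reverse** exchanges (arterial outlets
receive a dynamic-pressure body force steering their mean velocity toward
the factor-descaled venous consensus).

## Worked example: the 1:3 verification run

```sh
vasclbm run --config examples/one_to_three.toml
```

builds a single arterial channel and a three-branch venous tree, samples
the capillary pressure-drop fractions with the configured seed, derives
the velocity factors from the fixture's own link lengths, and advances
both instances 3000 steps with an exchange every 10 steps.  It prints

```
stability: pass (tau=0.6485, Ma=0.0450)
exchanges logged: 900
outputs in out/one_to_three
```

and writes `coupling_map.csv` (one row per link):

```
outlet_id,inlet_id,L,dP_frac,v_factor
1,0,0.0008178...,0.50472...,0.50864...
1,1,0.0015009...,0.68018...,0.37350...
1,2,0.0025013...,0.35766...,0.11785...
```

The three factors sum to 1 (equal boundary areas).  Averaging the last 100
steps of the patch time series gives achieved inlet/outlet velocity
ratios of 0.5086, 0.3735 and 0.1179 against imposed factors 0.5086,
0.3735 and 0.1179 — the coupled system reproduces the imposed scale
factors at steady state, which is the verification the 1:3 experiment is
designed to provide.  `exchange_log.csv` records every swap (step,
direction, per-link values) for auditing.

Other entry points: `vasclbm make-fixture {tube,one_to_n,bifurcating_tree}`
writes geometry containers, and `vasclbm analyze --state <state.h5>`
produces the velocity-versus-vessel-area table (signed negative areas mark
arterial vessels) from saved snapshots.

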