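# Methods

## Model and assumptions

The simulator resolves one periodic unit cell of superficial (papillary)
dermis. Lateral cell extent is `loop_width + loop_spacing` (240 μm standard)
in both directions; depth is the 800 μm slab of superficial dermis, chosen so
the much larger subcutaneous plexus below can be left out of the domain.
Coordinates: z positive downward, z = 0 at the top of the viable skin;
cell-centred nodes, 0-based indices, half-open layer intervals `[top,
bottom)`.

Assumptions carried by the model:

- Transport in avascular tissue is pure diffusion (`D_vs`); convective
  transport happens only inside the capillary loop and is fast compared with
  diffusion, so the lumen is reduced to a 1-D advected concentration along
  the centerline.
- The stratum corneum is not modelled; it is replaced by a constant applied
  flux `J_sc` at z = 0, the post-lag behaviour of most transdermal systems.
  `J_sc` is normalized to 1: the governing equations are linear, so every
  concentration scales with it and all reported ratios are independent of it.
- The subpapillary plexus is two well-stirred compartments (venule layer on
  top, arteriole layer below): the venule layer is stacked first because the
  capillary loops drain into the venule side before the blood reaches the
  arteriolar network. Spaces between plexus vessels are represented as
  avascular "pore" columns through both layers (area fraction = pore
  density), in which transport is plain tissue diffusion.
- Both loop limbs span from the apex depth to the plexus top. The anatomical
  loop proper is shorter (~215 μm from a 150 μm apex); the remainder of the
  venule limb stands in for the vertical venules that carry blood from the
  loop down to the plexus. Arteriovenous shunts, plexus branching, hair
  follicles, lymphatics and the deeper vasculature are out of scope.
- Zero initial concentration everywhere; periodic lateral boundaries
  (identical neighbouring unit cells); zero flux at the slab bottom (little
  concentration variation in deeper tissue), optionally a perfect sink for
  verification runs.

### Compartment balances

With `A_cl` the lumen cross-sectional area, `A_int` the (pore-corrected)
horizontal interface area and `V_vp`, `V_ap` the layer volumes:

    V_vp dC_vp/dt =  k_p A_vp (<C_vs>_top − C_vp) + A_int (k2 C_ap − k1 C_vp)
                     + k_pcl A_cl C_b(outlet)
    V_ap dC_ap/dt =  k_p A_ap (<C_vs>_bot − C_ap) + A_int (k1 C_vp − k2 C_ap)
                     − v_b A_cl C_ap − k_e C_ap,      k_e = v_b A_cl

Each transfer appears with opposite sign in exactly one donor and one
recipient balance, so mass is conserved term by term; the only exits from the
modelled system are the systemic removal `k_e C_ap` and, if `k_pcl ≠ v_b`,
the un-captured fraction `(v_b − k_pcl) A_cl C_b(outlet)` of the loop
outflow (zero at the default `k_pcl = v_b`). The loop inlet is fed at the
arteriole-plexus concentration (upwind ghost value `C_ap`), closing the
loop–plexus circuit.

## Parameters

| parameter | default | units | provenance / rationale |
|---|---|---|---|
| slab depth | 800 | μm | superficial dermis above the subcutaneous plexus |
| loop apex depth | 150 | μm | capillaroscopy of papillary loops |
| loop width / spacing | 170 / 70 | μm | capillaroscopy |
| loop length | 215 | μm | reported loop length; places the plexus at 300–400 μm |
| lumen diameter | 10 | μm | typical capillary-loop calibre; configurable (not reported) |
| plexus top depth | 400 | μm | loop depth + loop length |
| plexus thickness | 50 (25+25) | μm | maximal venous-capillary calibre plus branching |
| pore density `p_d` | 0.11 | — | standard vessel density of the plexus |
| `D_vs` | 1e-10 | m²/s | mid-range small-molecule dermal diffusivity; configurable (not reported); all acceptance ratios are insensitive to `J_sc` and only weakly shaped by `D_vs` |
| `D_p` | = `D_vs` | m²/s | pore transport is ordinary tissue diffusion |
| `v_b` | 6.5e-4 | m/s | measured loop blood velocity (0.65 ± 0.3 mm/s) |
| `k_p` | 1e-6 | m/s | endothelial permeability of the loop wall |
| `k1`, `k2` | `D_p/(T/2)` ≈ 4e-6 | m/s | inter-layer exchange as diffusion across half the plexus thickness `T`; no reported value |
| `k_pcl` | = `v_b` | m/s | convective delivery at the loop outlet, mirroring `k_e = v_b A_cl` |
| `J_sc` | 1 | amount·m⁻²·s⁻¹ | normalization (see above) |

`A_cl` uses the geometric circular area `π (d/2)²`. The rasterized
cross-section (node count × cell area, exposed as `lumen_cross_section`) is
kept as a verification measurement: it converges to the circular value under
refinement but jumps by whole cells at any fixed grid, and `k_e = v_b A_cl`
— hence every steady concentration level — must not inherit that noise.

## Discretization and solvers

- **Grid.** Structured cell-centred grid; every node carries exactly one
  label (tissue, arteriole/venule lumen, venule/arteriole plexus, pore).
  Diffusion is a 7-point stencil with harmonic-mean face conductances,
  periodic laterally; the applied flux enters the top cell layer as a source
  `J_sc/Δz`. Faces between tissue and lumen or compartment nodes carry no
  diffusive flux — those couplings are the explicit exchange terms.
- **Lumen chain.** The centerline is rasterized into ordered "stations" (one
  per grid cell along the three axis-aligned segments), thickened to
  `round(π r²/ΔxΔy)` nodes so the discrete cross-section tracks the circular
  one. Advection is conservative first-order upwind along the chain.
  Endothelial exchange distributes each station's lateral surface `π d Δs`
  equally over its diffusive 6-neighbours.
- **Pores** are whole tiles of a fixed ~10 μm lattice chosen by a seeded
  random priority order: deterministic for a given seed, nested (monotone) in
  density, and within half a tile (&lt;0.2% of cell area) of the requested
  fraction.
- **Time stepping.** The full coupled system is linear, `du/dt = A u + b`.
  Three schemes: `imex` (implicit diffusion via a cached sparse LU, explicit
  advection/exchange; default, `dt = min(½ Δs/v_b, ½/max rate)`), `explicit`
  (forward Euler, used for oracle cross-checks), `implicit` (backward Euler
  on all of `A`; unconditionally stable and positivity-preserving, for long
  transients). Advective-CFL violations are flagged at step time. All
  schemes conserve the discrete mass budget identically (to roundoff): the
  mass log tracks `total mass − (influx − removal)` relative to cumulative
  influx.
- **Steady state.** Solved directly from `A u = −b`. Unknowns in
  connectivity components the source never reaches (a stagnant impermeable
  lumen, compartments decoupled by `k_p = 0`) keep their zero initial value.
  The solution is accepted only if (i) the operational criterion — maximum
  residual rate × slab diffusion time / field magnitude — is below `tol`
  (default 1e-6), (ii) the global mass rate balances (influx = total
  removal to 1e-8), and (iii) concentrations are nonnegative; otherwise the
  result is flagged non-converged with a warning (e.g. pure accumulation
  with no removal pathway has no steady state). Direct solution was chosen
  because the slowest filling times of the deep dermis (10⁵–10⁶ s) exceed
  any practical number of advective CFL steps (~10⁻² s each); the
  time-stepping path remains the verification route.

## Verification

- **Dual implementation.** `verification.brute_force_*` re-implements the
  same continuous equations by naive array accumulation (rolls and
  per-station loops), sharing no discretization code with the operator
  assembly. One explicit step agrees to ~1e-16 relative; a 5 s horizon on the
  12×12×40 study grid agrees to &lt;1%; with `J_sc = 0` and `v_b = 0` the
  oracle conserves mass to 1e-16 over 100 steps.
- **Manufactured solutions.** A separable cosine eigenmode of the
  periodic/no-flux box decays at its analytic rate: observed spatial order
  ≥ 1.95 (7-point diffusion, with `dt ∝ h²`). A travelling wave with
  matching inlet history gives order ≈ 0.9–1.0 for the upwind advection.
  The fully coupled assembly with coupling coefficients at zero reproduces
  the diffusion orders exactly.
- **Closed forms.** With `k_p = v_b = 0`, a fully porous plexus band and a
  bottom sink, the steady solve matches `C(z) = J_sc (L − z)/D_vs` to
  ~1e-13 relative (the linear profile is in the stencil's null space).

## Sensitivity sweeps and read-outs

Depth profiles are sampled one grid cell laterally inward ("papilla side")
of each limb — the offset is a convention, not a reported value — with the
compartment concentrations reported across the plexus band and the local
blood concentration at lumen nodes on the line; `lateral_mean` averages each
depth slice with the compartments weighted by the discrete vascular area.
`C_plex` is the volume-weighted mean of `C_vp` and `C_ap`. The below-plexus
ratio uses the 50 μm band immediately below the arteriole layer; because the
band choice is a convention, the ratio is also reported for 25–100 μm bands
(`band_ratio_sensitivity`, and `below_plexus_ratio.csv` in CLI runs).

The sweeps change exactly one quantity each: plexus size scales both layers
symmetrically about the standard 425 μm mid-depth; plexus depth moves the
top with thickness fixed; velocity scales `v_b` (standard multiples 1/10,
1/4, 1/2, 3/4, 1); pore density re-draws the pore set at the new fraction
(nested, same seed). Default read-out is the steady state; a fixed-horizon
backward-Euler protocol (`protocol="horizon"`) is available to probe the
filling regime of the deep dermis.

## Known limitations

- **Below-plexus velocity ordering.** At steady state the only systemic exit
  is `k_e C_ap` with `k_e = v_b A_cl`, so the arteriole-plexus level is
  exactly `J_sc A_cell/(v_b A_cl)` and every concentration below the plexus
  scales like `1/v_b`: slower blood always means *higher* deep
  concentration, at steady state and (numerically, horizons 10³–10⁴ s) in
  transients. A model in which the deep dermis is additionally drained by
  vertical reticular venules would reverse this; those vessels are outside
  this domain. Observations attributing higher deep concentrations to faster
  blood therefore cannot be reproduced within this scope.
- The two-compartment plexus erases lateral structure within the layers;
  "adjacent to the venule/arteriole" differences inside the plexus band are
  not resolved, only immediately above and below it.
- First-order upwind advection is diffusive; the loop transit time (~1 s) is
  so short compared with tissue timescales that this has no visible effect
  on tissue profiles, but `C_b` wave shapes are smeared.
- At coarse grids the lumen is a single-cell chain; within one cell of the
  plexus top the venule/arteriole adjacency contrast is distorted (the 20 μm
  study grid reverses it at the 390 μm row only).
- Absolute concentration scales depend on the unpublished `J_sc` and on
  `D_vs`; only shapes, orderings and ratios are meaningful outputs.
- The coarse study resolution used in the test suite (20 μm with a 20 μm
  lumen, 12×12×40 nodes) and the 10 μm headline resolution (24×24×80) were
  chosen to keep full verification runs interactive; the below-plexus ratio
  changes by &lt;1 point between 10 μm and 8 μm.

## What the tests do and do not show

The suite validates the discretization (orders, oracle equivalence, closed
forms, conservation, positivity), the geometric invariants, and the
qualitative response of the model (venule-side enrichment at 350–400 μm,
concentration minimum at the plexus with a rise below it, monotone velocity
and pore-density responses, the ~30% below-plexus ratio). It does not — and
cannot — validate absolute concentrations against measured skin data: no
experimental dataset ships with the package, the applied-flux scale is
normalized, and the reference depthwise models are calibrated to the
simulation itself for shape comparison, not fitted to experiments.
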