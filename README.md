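# epidyn

Single-cell dynamics analysis of dense epithelial monolayers from tracked
nuclei.

Dense epithelia (mature barrier tissues, early tumours, confluent MDCK
monolayers at ~9400 cells mm⁻²) look mechanically arrested, yet they keep
remodelling. Whether their cells are truly caged like particles in a
thermal glass — or instead creep as a complex fluid — is decided by the
statistics of individual nucleus trajectories. `epidyn` implements that
full statistical toolkit for biologists and biophysicists who already have
tracking output (TrackMate CSV/XML or plain CSV of `track_id, frame, x, y,
θ`) and want the glass-physics analysis without writing it themselves:

- **Structure** — radial and nucleus-axis-aligned pair correlations g(r),
  static structure factor S(q), Voronoi neighbours, local density ρᵢ,
  nematic O²ᵢ and hexatic O⁶ᵢ order, per-cell two-body structural entropy
  Sᵢ = −(ρ/2)∫2πr[gᵢ ln gᵢ − gᵢ + 1]dr, coarse-grained field maps.
- **Dynamics** — translational / cage-relative / rotational MSD and
  Einstein diffusivity ⟨δr²⟩ = 4Dδt (with direction-resolved D(φ) relative
  to the nucleus long axis); self intermediate scattering function
  Fs(q,δt) = ⟨e^{i q·Δr}⟩ with exp[−(δt/τ(q))^β(q)] fits and the τ(q)
  power law; Van Hove function with Gumbel fit
  f(δx) = A(ζ)exp[−|δx|/ζ − e^{−|δx|/ζ}]; non-Gaussian parameter
  α₂ = ⟨δx⁴⟩/3⟨δx²⟩² − 1; displacement autocovariance; conditional
  step-memory statistics P(d₁₂∥|d₀₁); self-overlap
  Qᵢ(a,δt) = ⟨exp(−|Δrᵢ|²/2a²)⟩ₜ.
- **Heterogeneity** — top-10% fast cells clustered at cutoff r* = 15 μm;
  truncated power-law size law P(N_c) = A·N_c^−c·e^{−N_c/N_c*} fitted by
  discrete maximum likelihood; gyration-tensor diameter D_c and anisotropy
  ξ_c; fractal dimension N_c ∝ D_c^{d_f}; velocity-aligned correlation
  maps.
- **Events** — mean displacement, step series, spatial decay, aligned
  velocity fields and divergence around division/extrusion events versus
  seeded random controls.
- **Soft modes** — eigenmodes of the 2N×2N displacement covariance
  D_kl = ⟨u_k u_l⟩ from an early window, and the Pearson correlation of the
  per-cell mean low-frequency mode magnitude ⟨M⟩ (and of Sᵢ, ρᵢ, O²ᵢ, O⁶ᵢ)
  with the later-window self-overlap Qᵢ.
- **Synthetic tissue** — a seeded generator whose trap/creep model
  (Brownian cage centres + Ornstein-Uhlenbeck intracage motion; closed-form
  TMSD = 4D_cδt + 4σ_s²(1−e^{−δt/τ_r})) reproduces subdiffusive,
  anticorrelated creep crossing to Fickian-yet-non-Gaussian diffusion,
  heterogeneous and anisotropic mobility, clustered fast cells and
  transient division/extrusion boosts — so every stage is testable without
  experimental data.

## Worked example

`examples/05_division_events.py` injects division boosts (20 μm spatial
scale, 30 min time scale) into a diffusing monolayer and measures the
local dynamics around them:

```
65 division events injected
  dt = -30 min: <d_div> = 0.84 um, <d_ran> = 0.74 um
  dt = +30 min: <d_div> = 1.61 um, <d_ran> = 0.73 um
  (the event curve exceeds the control only after the division)
step series peaks at t = +0 min (0.78 um per 10 min)
recovered boost scales: spatial 18.8 um (injected 20), temporal 28.6 min (injected 30)
```

Before the division the neighbourhood moves like a random control region;
after it, the mean displacement roughly doubles, the per-10-min step
series peaks at the division moment, and fitting the excess against the
pre-event baseline recovers the injected spatial and temporal scales
within a few percent. The other scripts in `examples/` walk through the
creep/MSD diagnostics, structural order, fast-cell clusters, and the
soft-mode prediction of rearrangements the same way; each prints the
numbers it computes and one line on what they mean.

A full configured pipeline (synthetic input or a track file, all stages,
tidy CSV/JSON outputs and a summary report) is available from Python via
`epidyn.run_pipeline(PipelineConfig(...))` or from the shell:

```bash
epidyn synth --n-cells 800 --n-frames 200 --seed 1 --out synth_out
epidyn analyze --tracks synth_out/tracks.csv --out analysis_out
```

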