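# Methods

## Model overview

`commswarm` simulates *communicating active matter*: self-propelled agents
that align with neighbors and with the gradient of a diffusible chemical
signal which they themselves relay through an on-board excitable circuit
(a Schmitt trigger with a state-dependent threshold). The package contains
two complementary simulators and the quantification pipeline used to
characterize the hierarchical aggregation they produce.

### Excitable relay unit (`commswarm.signaling`)

Each agent carries a signal concentration `c` and a refractoriness state
`s`:

    ds/dt = eps (c - s)
    dc/dt = -alpha c + beta (1 - s) Theta(c - c_th(s)),   c_th(s) = (s + b)/a

`Theta` is the strict Heaviside function (no emission exactly at
threshold). The quiescent state (0, 0) is linearly stable; inputs above
`b/a` trigger a stereotyped excursion whose amplitude is set by the
phase-space flow, not by the input, followed by a refractory period
`tau ~ 1/eps`.

Excitability (excursion-and-return rather than latching into a sustained
"on" state) requires the threshold line to cut the production nullcline
below the would-be on-fixed-point: `s*(a - 1) < b` with
`s* = beta/(alpha + beta)`. The shipped defaults

| parameter | default | role |
| --- | --- | --- |
| `alpha` | 1.0 | signal degradation (1/time) |
| `beta` | 5.0 | release rate; `beta/eps >> 1` gives the relaxation-type pulse |
| `eps` | 0.05 | state relaxation; refractory period `~ 1/eps` |
| `a` | 0.5 | inverse threshold slope (`a < 1` guarantees excitability) |
| `b` | 0.2 | baseline threshold; quiescent threshold `b/a = 0.4` |

are repo defaults chosen to satisfy these regime constraints; the original
study's supplementary parameter table is not reproduced here. With them the
unit's peak response `c ~ 3.7` varies by < 1% over a factor-2 change of
input, and the state variable stays below 1 (so `s` is not clipped; for
exotic parameter sets that exceed 1 the dynamics is left unclipped and the
`1 - s` factor changes sign, which is outside the intended regime).

Integration is forward Euler (matching the reference scheme); tests verify
first-order step-size convergence and use finer-step and closed-form
oracles. The zero state maps to itself exactly (production is exactly
zero, no drift).

### Agent-based model (`commswarm.abm`)

N disk agents (radius `r_p`) in a periodic square of side L:

* positions: `dr_i/dt = v0 n_i` plus hard-core repulsion — overlapping
  pairs are shifted apart symmetrically along their distance vector until
  contact (`2 r_p`) is restored, sweeping pairs in ascending index order up
  to 10 times;
* headings: `dphi_i/dt = -Gamma sum_j sin(phi_i - phi_j)/r_ij + omega
  sin(phi_c - phi_i) + noise`, with neighbors within `r_c`, the signal
  gradient direction `phi_c`, and rotational diffusion `D_R`
  (Euler–Maruyama, one Gaussian draw per agent per step);
* the signal field lives on an M×M grid, integrated per Fourier mode by
  forward Euler; active agents deposit mass-conserving cloud-in-cell
  weights smoothed by a spectral Gaussian of width `w = 2 r_p`, so one
  quiescent active agent contributes exactly `beta` per unit time.

Choices the reference scheme leaves open, fixed here: `c` and its spectral
gradient are *bilinearly interpolated* to agent positions (spectral
evaluation at off-grid points costs far more for no visible benefit at the
grid resolutions used); gradients below `g_min = 1e-12` suppress the
chemotactic torque (atan2 of numerical noise is meaningless); headings are
wrapped to (-pi, pi] each step; neighbor search uses a periodic k-d tree
(equivalent to the virtual-cell grid, strict `<` cutoff). Update order per
step: headings/positions/overlaps, then source deposition from updated
positions, then the field step, then state relaxation against the updated
field.

The explicit field step requires `dt (D_c k_max^2 + alpha) < 2` with
`k_max = sqrt(2) pi M / L`; the integrator refuses to run outside it.

### Hydrodynamic model (`commswarm.hydro`)

Continuum fields (density `rho`, polarity `p`, signal `c`, state `s`) obey
an active polar fluid coupled to the same excitable medium; see the module
docstring for the equations. Density units put the mean-field critical
density of the isotropic–polar transition at `rho_c = 1`; uniform states
above it polarize with amplitude `sqrt(sigma (rho - 1)/delta)`. The
density–polarity coupling `Q(rho) = (v0/2)[exp(-32 rho) + exp(16 (rho-2))]`
acts as a low-density pressure (`v0/2`), nearly vanishes at intermediate
densities, and walls off the maximum packing density 2. The advection of
`s` uses the bounded factor `vbar = v0 tanh(|p|/rho)/|p|`.

Numerics: quasi-spectral on a periodic M×M grid with second-order
exponential time differencing (ETD2). The linear dynamics is a 5×5 matrix
per Fourier mode, integrated exactly; its `exp`, `phi1`, `phi2` matrix
functions are extracted jointly from one exponential of a 15×15 augmented
block matrix, which is exact for zero and defective eigenvalues without
eigendecomposition conditioning concerns. The nonlinear terms enter
through the two-step Adams–Bashforth ETD2 weights; the first step falls
back to ETD1. Consequences verified by tests: purely linear data follows
the matrix exponential to machine precision, the k = 0 density mode is
exactly inert (mass conserved to ~1e-16 over thousands of steps), uniform
fixed points of the discrete scheme coincide with the continuum ones, and
the observed convergence order on smooth problems is ~1.9.

Further numerical choices:

* **Threshold.** The printed production term has a sharp Theta; it is
  evaluated pointwise in real space (default). A smooth sigmoid of width
  `kappa` is available for convergence studies (the sharp version is not
  differentiable, which caps the observable ETD2 order there). The
  threshold argument is state-dependent, `c_th = (s + b)/a`, consistent
  with the well-mixed unit; a constant-threshold variant (`b/a`) is a
  switch.
* **Dealiasing.** 2/3-rule mask on the nonlinear products, on by default,
  switchable off.
* **Negative density.** Spectral ringing can push `rho` slightly negative;
  values in `(-neg_tol, 0)` (default `1e-8`) are clipped in snapshots.
  Deeper excursions raise by default (`neg_policy="error"`); production
  runs with sharp fronts use `neg_policy="clip"`, which warns instead —
  the nonlinear terms always see `max(rho, 0)`.
* **Initialization.** `rho0` plus exact-zero-mean white noise (default
  amplitude 1e-3), white-noise `p`, `s = 0`, and `c` seeded with randomly
  placed, randomly oriented anisotropic Gaussian kernels (major lengths
  20–30 units, width 5, amplitude `2 b/a` — twice the quiescent threshold,
  so nucleation fires).
* **Spiral seeding.** In a continuum model there are no fluctuations to
  re-ignite signaling: if all initial excitation fronts annihilate, the
  signaling field dies and aggregation stalls. Large domains develop
  spiral waves spontaneously through front collisions over long
  transients; desk-scale domains generally do not. `KernelSpec(...,
  spiral_seed=True)` therefore places a refractory strip in `s` along one
  flank of each kernel, so each outgoing front has free ends at birth and
  curls into a spiral pair. This is the standard excitable-media
  protocol for nucleating spirals deterministically and is used by the
  scaled-down demonstration runs.

### Scaled-down demonstration scenarios (`commswarm.scenarios`)

Two scale separations make the full vortex phenomenology expensive: polar
order grows at rate `sigma (rho - 1)` (thousands of time units at the
phase-diagram value `sigma = 0.02`), and a free spiral's pitch — wave
speed times the refractory period, roughly 35 length units at the default
signaling rates — is comparable to a 128-unit box, so unconfined spirals
self-annihilate within a few rotations and chemotaxis-built clusters are
irrotational "hedgehogs" (a polarity slaved to a gradient, `p ~ grad c`,
has zero curl). The scenario module prepares the configurations a long
transient would produce and lets the model evolve them:

* `vortex_regime_params()` — the vortex-forming corner of the phase
  diagram (low motility `v0 = 0.2`, elevated susceptibility
  `omega = 0.2`) with an intermediate polar relaxation rate
  `sigma = 0.1` (the regime described for vortex formation; the slower
  phase-diagram value needs ~10x longer runs) and weak saturation
  `delta = 0.02` so aggregates above the critical density carry
  substantial polar order.
* `add_ring_excitation(...)` — a dense annular aggregate with a
  unidirectional circulating pulse (the whispering-gallery mode that
  stabilizes ring states). A closed track longer than one wavelength
  supports the pulse indefinitely on an intact ring; as the circulating
  wave drags the local polarity tangentially, the super-critical ring
  retains that rotation, and the collapsing aggregate ends as a rotating,
  vortex-classified cluster (cluster-mean |curl p| ~ 0.015-0.022, above
  the 0.01 criterion). This is the ring-to-vortex route the model
  exhibits at full scale.
* `vortex_regime_demo(seed)` — both combined over a sub-critical
  homogeneous background: bulk kernels nucleate droplets and streams, the
  ring matures into the vortex, reproducing the droplet -> stream ->
  vortex hierarchy (droplet count peaks early, cluster number collapses
  much faster than 1/t in the streaming phase, the signal-field
  information trace returns to baseline before the density-field trace
  settles). One caveat on the last point: starting from a featureless
  state the density-field information *rises* toward its structured
  asymptote rather than decaying to a floor, so the meaningful desk-scale
  ordering is settling order, not floor-reaching order.

### Cluster analysis (`commswarm.clusters`)

Aggregates are 4-connected components (periodic wrap, 8-connectivity
switchable) of the strict `rho > 0.7` mask. Shape is measured from the
central moments of the binarized domain about the periodic-aware
(circular-mean) centroid; each pixel contributes its own square footprint
(`dx^2/12`) to the second moments, so a single pixel is exactly round and
thin lines keep a one-pixel minor axis. Axis lengths are equivalent-
ellipse diameters `4 sqrt(eigenvalue)`; third central moments are computed
and stored but unused by the default classifier. Mean polarity is the
cluster average of `p`; mean vorticity the cluster average of the spectral
curl. Note that for a compactly supported rotating cluster the boundary
circulation sheet partially smears into the mask, so the cluster-mean
vorticity is systematically below the interior value `2 A / R` of a rigid
vortex — both are positive and well above the 0.01 criterion in practice.

Classification: *stream* iff shape factor > 1.4 and the major-axis/mean-
polarity angle (folded to [0, pi/2]; the axis is undirected) < pi/4;
*vortex* iff shape factor < 1.4 and |mean vorticity| > 0.01 (either
handedness); *droplet* otherwise, with all boundary equalities resolving
to droplet per the strict inequalities.

Coarsening kinetics: the mean-field coalescence model
`dn/dt = -D0 S^gamma n^2` with `S ~ 1/n` gives `N_c ~ t^(-z)`,
`z = 1/(1 - gamma)`; `gamma = 0` is interface-controlled ripening
(`N_c ~ 1/t`). Fits: log–log least squares (power), linear least squares
on `N_c t = N0 - kappa t^2` (streaming phase), and `N_c = A/ln t`
(vortex-competition phase). The aggregation time `T_aggr` defaults to the
first (linearly interpolated) time the maximum density crosses
`rho_c = 1`; "fraction of mass above rho_c" is an easy variant but the
maximum-density criterion is the implemented default, and a never-crossed
series returns `None`.

### Information content (`commswarm.information`)

The computable information content of a configuration is the byte size of
its losslessly compressed 8-bit encoding. Fields are block-averaged
(anti-aliased; nearest-neighbor switchable) to 128×128, affinely quantized
to 256 gray levels by `floor((v - min)/(max - min) * 256)` clipped to 255,
tiled in the fixed order (rho, p_x, p_y, c, s) — polarity enters as
components — and compressed with DEFLATE at a fixed level (the codec
behind PNG; only the compressed stream is measured, no container
headers). Quantization ranges are fixed per run, not per frame, so I(t)
is comparable over time. Both the collective mosaic and per-field images
are measured; the per-field sizes feed the field-by-field analysis.

The processing rate `R` is the area fraction with `c > 1` (strictly), and
the information balance `dI/dt = gamma_R R - lambda I` is fit by
integrated-trajectory least squares over `(lambda, gamma_R, I0)` with
non-negativity bounds. The direct regression of central-difference
`dI/dt` on `(R, -I)` is retained as `method="derivative"`, but it is
attenuation-biased when I carries measurement noise (the noise enters
both sides of the regression) and under 5% multiplicative noise it
understates `lambda` by tens of percent, so the trajectory fit is the
default.

### Fixtures (`commswarm.fixtures`)

Synthetic test surfaces with known ground truth: planted droplet / stream
/ vortex fields (background density 0.6, aggregate 1.5; rigid azimuthal
polarity for the vortex, axis-aligned polarity for the stream), cluster-
number series drawn from a chosen coarsening law, and information traces
generated from the rate model with known `lambda`. Optional i.i.d. noise
emulates measurement scatter only — these fixtures have none of the
spatial correlations, interface structure or wave dynamics of real
simulation output, so classifier scores on them bound pipeline
correctness, not real-data performance.

## Problem sizes

The demonstration and acceptance runs are deliberately desk-scale — the
package's own choice of default problem sizes: 64^2 grids for the
critical-density cross-check, a 128^2 grid (L = 128, dt = 0.05, a few
thousand time units) for the aggregation phenomenology, and 10^3–10^4
agents for the agent-based statistics, versus production-scale runs
(t_sim = 40,000, snapshot interval 200) configured in the shipped
defaults. Scaled-down runs keep the same dimensionless regime (density
0.6, vortex-forming balance of motility and signal susceptibility) but
fewer structures and fewer decades of coarsening, so power-law windows
are short and the late logarithmic stage is only indicated, not resolved.

## Known limitations

* The coarse-graining derivation connecting the agent model to the field
  theory is not part of the package; the two models are implemented
  independently and compared only phenomenologically.
* Sharp-threshold production injects high wavenumbers; dealiasing and the
  snapshot clip policy manage, but do not eliminate, spectral ringing
  around steep fronts.
* The agent-based simulator is pure NumPy/SciPy; it is comfortable at
  N ~ 10^4 but not tuned for production-scale swarms.
* Compressed size depends on the codec configuration; only differences
  and trends of I(t) under the fixed configuration are meaningful.
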