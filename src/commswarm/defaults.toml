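# Default parameter set shipped with commswarm.
#
# Values tagged "paper" in [provenance] come from the reference study's
# printed settings (domain/step sizes, sigma, rho0, the Fig-3 operating
# point v0 = 0.5, omega = 0.05, and the output schedule).  All remaining
# values are repo defaults: the original supplementary parameter tables are
# not available, so rates were chosen to satisfy the stated regime
# constraints (beta/epsilon >> 1 for a relaxation-type excitable response,
# fast signal diffusion D_c/(r_p v0) >> 1, alpha of the same order as the
# mean source strength).

model = "hydro"
seed = 0

[abm]
v0 = 0.5
Gamma = 0.1
omega = 0.5
D_R = 0.05
r_p = 0.5
r_c = 1.5
L = 200.0
N = 4000
dt = 0.01
M = 200
D_c = 5.0

[hydro]
v0 = 0.5
D_rho = 0.2
sigma = 0.02
delta = 0.02
D_p = 0.2
chi = 0.01
omega = 0.05
D_c = 5.0
alpha = 1.0
beta = 5.0
epsilon = 0.05
a = 0.5
b = 0.2
M = 128
L = 128.0
rho0 = 0.6
dt = 0.05
noise_amplitude = 0.001
theta_mode = "sharp"
kappa = 0.02
dealias = true
neg_policy = "error"
neg_tol = 1e-8

[signaling]
alpha = 1.0
beta = 5.0
epsilon = 0.05
a = 0.5
b = 0.2

[schedule]
t_end = 40000.0
snapshot_interval = 200.0

[output]
path = "snapshots.h5"

[analysis]
clusters = true
information = true

[provenance]
"abm.v0" = "paper"
"abm.L" = "paper"
"abm.N" = "paper"
"abm.dt" = "paper"
"abm.M" = "paper"
"hydro.v0" = "paper"
"hydro.sigma" = "paper"
"hydro.omega" = "paper"
"hydro.rho0" = "paper"
"schedule.t_end" = "paper"
"schedule.snapshot_interval" = "paper"
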