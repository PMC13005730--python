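# Simulation configuration for `jmncc simulate/experiment --config ...`.
# Keys mirror jmncc.SimConfig; omitted keys keep their defaults.

N: 2000                # cohort size
n_cases_target: 100    # cases kept by the administrative censoring step
K: 2                   # number of competing causes

family: normal         # longitudinal family: normal | poisson
link: identity         # identity (normal) | log (poisson)
gamma: [0.0, 0.5]      # fixed effects: intercept, time slope
sigma2: 1.0            # residual variance (normal family)
random_effects: intercept   # intercept | intercept_slope
theta_var: 1.0         # random-intercept variance
theta_slope_var: 0.04  # random-slope variance (intercept_slope only)
theta_cov: 0.0         # intercept-slope covariance

knots: [.inf]          # piecewise baseline cutpoints (last piece extends)
xi:                    # baseline hazard per cause per piece
  - [0.0161]
  - [0.0080]
beta: [0.0, 0.0]       # biomarker association per cause (scenario 1: null)
alpha:                 # binary-covariate effect per cause
  - [0.3]
  - [0.2]

censor_lo: 0.0         # step-1 random censoring ~ Uniform(lo, hi)
censor_hi: 5.0
grid: 0.25             # biomarker measurement spacing
m: 1                   # controls per case for pipeline helpers
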