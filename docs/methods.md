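# Methods

## Problem and model

The package solves, by physics-informed training, the steady
incompressible Navier–Stokes equations in a family of 2D symmetric
channels of length L = 1 m whose half-width is

R(x) = R0 − A·exp(−(x − μ)²/(2σ²)),  R0 = 0.05 m, μ = 0.5 m,

with the centerline at y = 0 and walls at y = ±R(x). The case vector
λ = (A, σ) spans A ∈ [0.015, 0.035] m and σ ∈ [0.10, 0.18] m; A = 0 is
the degenerate straight channel used for analytic verification. Boundary
conditions: parabolic inlet u = u_max(1 − y²/R_inlet²) with
u_max = 0.00925 m/s, v = 0 at the inlet; p = 0 at the outlet; no slip at
the walls. Fluid: ρ = 1000 kg/m³, ν = 1.85·10⁻⁶ m²/s (water-like;
Re = u_max·2R0/ν = 500 at the inlet). All constraints are soft: they
enter the loss as mean-squared residuals at sampled collocation points,
never by construction of the output function.

Every loss term is unit-normalized with V_kg = 1 kg, V_m = 0.1 m (the
inlet diameter) and V_s = 10.811 s (chosen so V_m/V_s equals u_max to
four significant figures): continuity residuals are multiplied by V_s,
momentum residuals divided by V_m·V_s⁻², velocity BC residuals by
V_m·V_s⁻¹ and the pressure BC by V_kg·V_m⁻¹·V_s⁻². With this
normalization all loss weights default to 1. Each BC term averages over
its own point count; the two walls are pooled into one no-slip term, and
the wall term averages the squared velocity *magnitude* per point (the
u and v components share points, they are not separate samples).

## Architectures

All networks are fully connected with SiLU activations and an affine
output layer producing (u, v, p). Three case-conditioning schemes:

- **mixed** — one network on (coordinates, TSCs, A, σ).
- **hypernetwork** — f_h(λ) emits the flattened weights and biases of the
  main network f_m(x); only θ_h is trainable. The head of f_h is a
  32-wide five-layer stack, a penultimate feature layer (10 wide at the
  large budget, 3 at the downsized budget) and a final affine map to the
  full parameter vector of f_m.
- **modes** — f_h(λ) emits a bank of B modes ℳ (B × 3) and f_m(x) emits
  mode weights q; the output is the inner product ŷᵢ = Σⱼ qⱼℳⱼᵢ. B is
  chosen by brute-force search at build time as the largest integer
  keeping the total parameter count within +0.1 % of the mixed budget
  (B = 852 at the large budget, 517 downsized).

`input_bias` controls whether the first trainable hidden layer carries a
bias vector. The published single-case counts (445,443; 790,531;
3,153,923; 200,707) are reproduced exactly only *without* that bias; the
multi-case mixed counts (2,214,475; 808,575) only *with* it and 12
inputs. Both conventions are therefore exposed explicitly, defaulting to
no first-layer bias for single-case replicas and bias-present for
multi-case ones. Under the adopted head convention the hypernetwork
totals come out 32 lower than the printed 2,215,275 / 808,303 (within
0.004 %); no single bias/head convention we found reproduces those four
printed totals exactly, so the match is documented as approximate.

Inputs are affinely normalized to O(1) before the first layer (x by the
half-length, y by R0, A and σ by their range midpoints/half-widths;
TSCs are already O(1)), and the three outputs are scaled by fixed
constants (u_max for velocities, V_kg·V_m⁻¹·V_s⁻² for pressure) so the
normalized losses are O(1) at initialization. These scalings are fixed
(non-trainable) and do not change parameter counts.

Initialization is variance-scaling (std 1/√fan_in) with zero biases,
seeded. The hypernetwork's final layer starts with near-zero weights and
a bias equal to a standard initialization of the generated main network,
so training begins from a sensible f_m with weak case dependence.

## Tube-specific coordinates

Eight derived inputs: c = 2x/L − 1; Lₙ = y/R(x) (locally normalized, so
Lₙ = ±1 exactly on the walls everywhere, including the throat);
d² = 1 − Lₙ²; and c², Lₙ², c·d², c·Lₙ, Lₙ·d². In laminar tube flow the
solution is nearly quadratic across the width (the straight-channel
solution is exactly u = u_max·d²), so pre-computing these second-order
combinations removes approximation burden from the network.

## Exact derivatives

No external autodiff framework is used. Two small, composable pieces:

- `tubepinn.autodiff` — a numpy-backed reverse-mode tape (elementwise
  arithmetic with broadcasting, matmul, exp, logistic, reductions,
  concatenation, slicing) that supplies gradients of the scalar loss
  with respect to the trainable parameters.
- `tubepinn.jets` — forward-mode propagation of a sparse set of
  derivative channels: first order in (x, y, A, σ), second order (xx,
  yy, and the mixed xA, yA, xσ, yσ), and the mixed third order (xxA,
  yyA, xxσ, yyσ). Channel payloads may be arrays or tape tensors, so a
  single reverse pass over the forward-propagated channels yields
  parameter gradients of losses that themselves contain exact
  derivatives.

The channels are exactly those the losses consume: the viscous terms
need xx and yy; the gPINN loss needs d/dλ of residuals that contain
second spatial derivatives, hence the mixed third-order channels. TSC
features, wall positions y = ±R(x; λ) and the inlet target are built
from the same jet arithmetic, so their geometric dependence on (A, σ) is
differentiated exactly rather than approximated. SiLU derivatives up to
third order are expressed through the logistic function so that they
remain differentiable in reverse mode.

All derivative paths are verified against central finite differences in
the test suite (spatial: relative 1e−4 at step 1e−4 on normalized
coordinates; case derivatives: relative 1e−3 at step 1e−5), and the
analytic Poiseuille solution run through the full machinery yields
physics + BC losses at the 1e−36 level (pure rounding error).

## gPINN derivative loss

The printed derivative loss is a raw mean of dR/dλ, which can be
negative and is therefore not usable as a loss; following the gPINN
literature the implementation uses the mean of *squared* derivative
components. Derivatives are taken of the already unit-normalized
residuals, with each case parameter normalized by its range width
(0.020 m for A, 0.08 m for σ), so the term is dimensionless;
ω_derivative defaults to 1. The boundary term is evaluated on all
boundary regions (walls, inlet, outlet). The two-phase schedule trains
with the plain loss first and resumes with the derivative term active;
when ω_derivative = 0 the derivative graph is skipped entirely, which
keeps the zero-weight phase bit-identical to continued plain training.

## Training

Adam (β = 0.9/0.999, lr 1e−3 with cosine decay to 1e−5 per fit call,
both configurable) on batches of (inlet, outlet, wall_top, wall_bottom,
interior) = (160, 160, 160, 160, 3200) points per iteration — 3840
total, 3.84 million per 1000-iteration epoch. Interior points are drawn
per iteration from a pre-generated per-case pool `pool_factor` (default
1000) times the per-case quota, refreshed every epoch; boundary points
are sampled fresh (walls uniformly in arc length via an inverse-CDF
table, though for these gentle slopes arc length is nearly uniform in
x). In multi-case training each region quota is split evenly across the
training cases with round-robin remainders. Runs are reproducible: a
single integer seeds initialization and sampling, and pure-numpy
execution is deterministic. A divergence guard aborts when the total
loss exceeds 10⁶ × its initial value for 100 consecutive steps.

Case grids: training is the Cartesian product of 4 arithmetically
spaced A values and 4 logarithmically spaced σ values (16 cases,
endpoints included; the σ set's geometric mean is √(0.10·0.18) ≈ 0.134).
Validation is 9 A values at arithmetic half-offsets × 5 σ values at
logarithmic half-offsets (45 cases), strictly interior and therefore
disjoint from training by construction; the exact validation layout is
an assumption and is configurable.

## Evaluation

Relative L2 error ε = 100·‖ŷ − y‖₂/‖y‖₂ on N seeded uniform interior
points per case (default 10,000). For references with identically zero
v (the analytic straight channel) ε_v is normalized by ‖u‖ instead, and
a zero reference raises an explicit error. Wall shear stress uses the
printed convention WSS = μ·|(∇v + ∇vᵀ)/2 · n̂| — half the conventional
Newtonian traction for simple shear — with a `conventional_2x` flag for
the factor-2 variant; wall normals are computed analytically from dR/dx
rather than assumed vertical, which matters at the narrowing shoulders.
For the straight channel the closed forms are WSS = μ·u_max/R0 =
3.4225·10⁻⁴ Pa at the wall and p(0) = 2ρνu_max·L/R0² = 0.013690 Pa at
the inlet. External reference fields load from CSV or legacy-ASCII VTK
point clouds (a purpose-written ~50-line reader; no installed library
parses VTK) with barycentric-linear interpolation and nearest-point
fallback, recording the method used.

## Verification scale and what it shows

The desk-scale recovery benchmark trains a 3×64 mixed network on the
A = 0 case with (64, 64, 64, 64, 256)-point batches, evaluating ε_u on a
50×50 grid every 500 iterations; with TSC inputs it reaches ε_u < 5 %
in roughly 2.5–3.5 k iterations (a few minutes on one CPU) and
consistently needs fewer iterations than the same-size network without
TSC — the qualitative TSC advantage at small scale. The full published
study trains ~2.2 M-parameter networks against external CFD ground
truth over 61 cases; those error tables and convergence-time figures
require GPU-scale training and a CFD solver and are out of scope here.
Passing the desk benchmark demonstrates correctness of the losses,
derivatives and optimization loop, not the accuracy attainable at full
scale.

## Known limitations and open points

- The printed kinematic viscosity "1.85 m³/s" has impossible units; the
  implementation adopts 1.85·10⁻⁶ m²/s, which gives inlet Re = 500. The
  quoted Reynolds range 375–450 is not reproducible from any stated
  convention (local vs inlet radius, mean vs peak velocity) and is left
  as an open question.
- Geometry is a single symmetric Gaussian narrowing in a straight 2D
  channel; no curvature, asymmetry, multiple narrowings or 3D.
- The channel length is not stated in the source description; L = 1 m is
  adopted (consistent with μ = 0.5 and c spanning (−1, 1)) and
  configurable.
- Dynamic loss weighting, adaptive activations, Fourier features and
  hard boundary constraints are deliberately excluded.
- The numpy execution model is single-threaded and CPU-bound; it is
  sized for verification, not for the multi-million-parameter regime.
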