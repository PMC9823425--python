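# Methods

## Problem and model

`csifem` reconstructs the complex permittivity distribution inside a head-
like phantom from multistatic microwave measurements at ~1 GHz, the setting
of quantitative brain-stroke imaging. The forward model is the frequency-
domain vector wave equation for the scattered electric field,

    curl curl E_t^sct - kb^2 E_t^sct = kb^2 w_t ,     kb^2 = omega^2 mu0 eps0 eps_b ,

with the time convention `exp(+j omega t)` so passive media have
`Im(eps) <= 0` and `eps = eps_r - j sigma/(omega eps0)`. The inverse problem
is solved by contrast source inversion (CSI): the contrast
`chi = (eps_target - eps_b)/eps_b` and the contrast sources
`w_t = chi E_t^tot` are updated alternately to minimize
`F_CSI = F_S + F_D`, the sum of a data-mismatch term over the antenna ports
(S domain) and an object-equation term over the imaging volume (D domain).

## Discretization

The domain is a box meshed by splitting every cell of a uniform hexahedral
grid into six tetrahedra around the same main diagonal (Kuhn subdivision;
conforming and fully deterministic). Fields are expanded on lowest-order
curl-conforming Whitney edge elements, oriented globally from the lower to
the higher node index, so no per-cell sign bookkeeping arises. All element
integrals (curl-curl stiffness, kb^2-weighted mass, cell averages of the
basis, and the boundary tangential-trace mass) are closed-form; each is
validated against an independent quadrature oracle in the test suite. The
permittivity is sampled at cell barycenters and held constant per cell. The
outer boundary carries a first-order absorbing condition
`j kb (n x N_i).(n x N_j)` integrated over the boundary triangles; the
boundary sits >= lambda/4 beyond the phantom in the default geometries.
Antennas are modelled either as elementary dipoles (default; excitation by
Galerkin testing of a point current, reception by field sampling at the
receiver position) or as annular coaxial ports whose received field is
projected on the normalized TEM mode `e_TEM = rho_hat / (rho sqrt(2 pi
ln(rb/ra)))`; scattered data are differences of target- and background-
scenario port responses. Source and receiver use identical spatial
weightings, which makes simulated data reciprocal to solver precision.

## Contrast-source representations

Two discretizations of `w_t` are implemented behind one interface:

* **standard** — one 3-vector coefficient per cell,
  `w_t,i = chi(r_i) E_t(r_i)`, paired with an E x I coupling matrix of
  cell-averaged basis integrals. The contrast source is constant per cell,
  discarding the linear field variation.
* **edge basis** — 6I scalar coefficients on the cell-restricted Whitney
  functions `N_e p_i`: slot `(i, le)` holds `E_t,e chi_i`. The coupling
  matrix R is then the ordinary scalar sparse matrix of kb^2-weighted
  Whitney mass blocks, and the representation is *exactly consistent* with
  the discretized wave equation: because `kb^2 chi = k^2 - kb^2` cell-wise,
  `R w_exact = (V_target - V_background) E_tot` holds to machine precision,
  so the wave-equation residual and the exact-point cost functional are
  limited only by the forward-solver tolerance. Freezing the basis at the
  cell barycenter ("barycenter" evaluation mode) reproduces the standard
  scheme inside the same scalar machinery; the inversion's "standard"
  variant uses exactly this mode, so both variants share one code path and
  any performance difference is attributable to the discretization alone.

## Forward solver

The system matrix `K = U - V - A` is complex symmetric and contrast-
independent, so one factorization (or preconditioner) serves every
transmitter and every inversion iteration; adjoint solves use
`K^H x = b <=> x = conj(K^-1 conj(b))`.

Small and unstructured problems use a sparse LU (SuperLU in symmetric
mode). A 3-D direct factorization becomes impractical beyond ~10^5 edges on
a single CPU, so structured meshes switch (at 40k edges under the `auto`
policy) to a preconditioned GMRES built from the grid structure: the
constant-coefficient periodic operator is block-circulant over the 7 edge
translation classes of the Kuhn split and diagonalizes under a 3-D FFT into
7x7 blocks. The preconditioner combines (multiplicatively) the inverse of
this symbol — computed for a reference medium `mean(kb^2)(1 - j beta)`,
`beta = 0.1` by default, the complex rotation damping near-resonant modes —
with an exact sparse solve on a two-cell-layer boundary shell that corrects
the periodic/absorbing-boundary mismatch. The torus is padded by two cells
so boundary edges map injectively. GMRES (restart 500) with this preconditioner
reaches ~1e-12 relative residuals in 100-600 iterations on the study
geometries; `solve()` verifies the achieved residual, warns above 10x the
target and fails above 1000x. The `beta` rotation is increased
automatically if the symbol is near-singular (lossless reference media).

## Inversion

The update scheme is the canonical CSI of van den Berg and Kleinman:

* initial guess by backpropagation, `w_t,0 = gamma_t G_S^H d_t` with the
  closed-form one-parameter minimizer
  `gamma_t = ||G_S^H d_t||^2 / ||G_S G_S^H d_t||^2` (the functional is
  undefined at `w = 0`, where `F_S = 1` by construction);
* one Polak-Ribiere conjugate-gradient step per transmitter on `w` with an
  exact line search (the cost is quadratic in the real step, so the
  minimizing step length is closed-form); one adjoint and one forward
  solve per transmitter per iteration;
* cell-wise least-squares contrast update
  `chi_i = sum_t conj(E_t,i) . w_t,i / sum_t |E_t,i|^2` with
  `E_t = E^inc + G_D w_t`, restricted to the domain of interest; cells
  with denominator below 1e-30 keep their previous value;
* the F_D normalization `sum_t ||chi_n E_t^inc||^2` is recomputed with the
  current contrast each iteration;
* no regularization term (a hook exists in the configuration); iteration
  stops early if the cost increases five consecutive times.

Norms in both cost terms are plain Euclidean norms of coefficient arrays,
the same convention as the residual metrics; with exact line search the
logged `F_CSI` is non-increasing, which the suite asserts.

## Synthetic scenarios

The generator emulates the desk-scale acquisition the package is tested
under: a head sphere of radius 50 mm with the average head properties
(eps_r = 45.37, sigma = 0.77 S/m) centred in a 140 mm box of coupling
medium (eps_r = 20, sigma = 0), a blood-like ellipsoidal inclusion
(eps_r = 64.41, sigma = 1.58 S/m at 1 GHz) standing in for a haemorrhagic
stroke, 8 antennas on an equatorial ring of radius 60 mm, and 1 GHz
throughout. Scattered data are simulated on a mesh (default h = 4 mm)
different from the inversion mesh (default h = 5 mm) so the inversion
never sees data produced on its own discretization; requesting equal
meshes without an explicit override warns about the inverse crime. Noise,
when enabled, is complex circular Gaussian per datum with the standard
deviation set by an SNR in dB relative to the per-transmitter data norm;
the default is noiseless and the whole pipeline is bit-deterministic given
the configuration and seed.

What the generator does *not* emulate: anatomical multi-tissue phantoms
(a single homogeneous head layer plus inclusion replaces them — the
discretization comparison does not depend on shape realism), dispersive
tissue models, fabricated-antenna effects, or measurement calibration.
Passing tests therefore demonstrate correctness of the discretizations,
operators and optimization on controlled scenes, not clinical performance.

## Problem sizes and numerical choices

The accuracy experiments (wave-equation residual, scattered-coefficient
recovery, exact-point costs) run on the homogeneous-head fixture at
h = 5 mm (160,804 edges) with 4 antennas and forward tolerance 1e-12; the
background scenario for these consistency tests is the coupling medium
alone, so the whole head is the contrast. Behavioural and recovery tests
use 90-120 mm scenes at h = 7.5-20 mm with 4-6 antennas; the low-contrast
recovery run uses an inclusion with |chi| <= 0.2, data mesh h = 7.5 mm
and inversion mesh h = 9 mm over 100 iterations. Degenerate inputs are
rejected early: zero-volume cells name the offending cell, non-closed
boundaries and passivity violations raise, and direct solves verify their
residual so a singular system cannot return silently.

## Known limitations

* The FFT-preconditioned path requires the structured box mesh with equal
  cell counts per axis; imported unstructured meshes fall back to the
  direct solver and are size-limited by memory.
* First-order absorbing boundaries reflect a few percent at oblique
  incidence; quantitative comparisons keep the boundary placement fixed
  across compared variants, so the bias cancels in orderings.
* CSI underestimates high contrasts (a known property of the method); the
  recovery assertions are therefore directional (error decreasing,
  inside/outside ordering) rather than absolute.
* Single frequency per run; no multi-frequency or multiplicative-
  regularized variants.
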