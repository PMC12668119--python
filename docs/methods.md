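# Methods

## Model

Each voxel is modeled as a mixture of up to three white-matter (WM) fiber
populations plus two isotropic compartments, gray matter (GM) and free water
(FW). For diffusion weighting b (s/mm²) and unit gradient direction g, the
noiseless attenuation (S0 = 1) is

    S(b, g) = Σ_i [ f_in,i ∫ p_i(n) exp(−b D∥ (g·n)²) dn
                  + f_ex,i ∫ p_i(n) exp(−b (D⊥ex + (D∥ − D⊥ex)(g·n)²)) dn ]
            + f_GM exp(−b D_GM) + f_FW exp(−b D_FW),

with Σ_i (f_in,i + f_ex,i) + f_GM + f_FW = 1. The intra-axonal compartment
is a stick (zero radial diffusivity); the extra-axonal compartment is an
axially symmetric zeppelin; intra- and extra-axonal axial diffusivities are
shared (a single D∥ per voxel). Each fiber's orientation density p_i is a
Bingham distribution; the default is the axially symmetric case
(κ₁ = κ₂ = κ, i.e. Watson), parameterized by the orientation dispersion
index through the standard mapping ODI = (2/π)·arctan(1/κ). Anisotropic
dispersion (κ₁ > κ₂) is implemented but never sampled.

The spherical integrals are discretized as probability-weighted sums over a
fixed orientation grid (below), with the uniform quadrature weight absorbed
into the density normalization. This replaces the Bingham normalization
constant with a discrete sum and is a consistent estimator of the continuous
integral because the grid is near-uniform by construction.

## Orientation grid

Fiber axes are sampled from, and the dispersion integral evaluated on, a
724-vertex electrostatic grid: vertices placed by projected gradient descent
on the Coulomb (inverse-distance) energy in which every vertex also repels
every antipode, so the 724 vertices are 724 *distinct orientations* rather
than antipodal pairs. The descent starts from a deterministic golden-spiral
configuration and only accepts energy-decreasing steps (backtracking line
search), so the construction involves no randomness, the energy trace is
non-increasing, and the result is reproducible bit-for-bit. The converged
724-vertex set ships with the package as plain text; the builder is used
directly for other grid sizes.

On this grid the mean great-circle angle from a vertex to its nearest
neighbor is 5.63° under the plain convention and 5.48° with antipodal
folding (both computed by `nearest_neighbor_resolution`). For reference,
the idealized hexagonal-packing spacing for 724 orientations (1448 points)
is 5.74°; other resolution summaries in use quote roughly half the spacing
of a 362-orientation/724-vertex paired grid (≈ 8.2°/2 ≈ 4.1°), i.e. the
worst-case snapping error of an arbitrary axis onto the grid — a different
statistic from the nearest-vertex mean reported here.

## Sampling priors

One dictionary entry is drawn as follows (defaults, "in vivo" regime):

| parameter | prior | notes |
|---|---|---|
| number of fibers N | uniform on {0, 1, 2, 3} | |
| (WM, GM, FW) fractions | Dirichlet(2, 1, 1) | N = 0: WM = 0, (GM, FW) ~ Dirichlet(1, 1) |
| fiber axes | uniform over grid vertices | pairwise folded separation ≥ 10° |
| fiber weights | N=2: (w, 1−w), w ~ U(0.2, 0.8); N=3: Dirichlet(1,1,1) | share of the WM fraction |
| ODI per fiber | uniform over 10 equispaced values on [0.01, 0.30] | independent per fiber |
| intra-axonal fraction | U(0.6, 0.9) | shared across fibers in a voxel |
| D∥ (in vivo) | U(2.0, 3.0)×10⁻³ mm²/s | shared intra/extra |
| D⊥ex (in vivo) | U(0.1, 1.5)×10⁻³ mm²/s | |
| D∥, D⊥ex (ex vivo) | U(0.6, 1.0)×10⁻³, U(0.01, 0.35)×10⁻³ | |
| D_GM, D_FW | fixed 1×10⁻³, 3×10⁻³ mm²/s | |

A "disco" preset narrows the bands to stick-phantom values
(D∥ ~ U(0.54, 0.66)×10⁻³, D⊥ ~ U(0.32, 0.38)×10⁻³) and disables the
isotropic compartments, for purely fibrous numerical phantoms.

Design choices where the design was genuinely open: one diffusivity pair is
shared by all fibers of an entry (reduces degeneracy and matches common
fingerprinting practice); ODI is drawn independently per fiber; the
intra-axonal fraction is shared within an entry; fiber-free voxels redraw
(GM, FW) with a flat Dirichlet because a WM fraction without fibers is
undefined in the mixture; the 10° minimum axis separation mirrors the
minimum peak separation used in evaluation and prevents duplicate-axis
degenerate entries; two-fiber weights are not ordered.

The production dictionary size is 500,000 entries (estimates converge well
before this; differences between 500 k and 1 M are negligible). Tests and
the bundled benchmarks use 2,000–100,000 entries, which keeps the full suite
within minutes on one CPU while leaving recovery behavior qualitatively
unchanged. Sub-b0-threshold volumes with nonzero b retain their (tiny)
attenuation; columns with b exactly 0 are stored as exactly 1.

## Matching

Voxels are matched in signal space by cosine similarity
C_i = (y·S_i)/(‖y‖‖S_i‖) against pre-normalized dictionary rows. Cosine is
scale-invariant — cos(γy, d) = cos(y, d) for γ > 0 — and equivalent to the
optimally rescaled ℓ₂ misfit through
min_β ‖y − βd‖² = ‖y‖²(1 − cos²(y, d)), which removes the need for unstable
b0-based intensity normalization. All volumes, including every b0, enter the
matching vector; nothing is averaged. The K = 50 most similar entries (ties
at the boundary broken toward the lower index) form a candidate
neighborhood, within which the selected entry maximizes
cos − α·n_fibers, α = 10⁻⁵ by default; exact ties prefer fewer fibers, then
the lower index. Negative cosines are kept.

Numerical contract: each voxel's similarity profile is computed as one
matrix–vector product, so results are bit-identical under any block
partitioning or parallel split. Selection is exhaustive over the dictionary
(no approximate nearest-neighbor stage). All-zero voxels are flagged
unmatchable and excluded from maps.

## Derived maps

All outputs are deterministic functions of the matched configuration.
Because the configuration is a finite Gaussian mixture (per fiber and grid
vertex: a stick tensor D∥ n nᵀ weighted f_in·p̂_j and a zeppelin tensor
D⊥ex I + (D∥ − D⊥ex) n nᵀ weighted f_ex·p̂_j; plus the two balls), its
diffusion and kurtosis tensors are closed-form mixture moments rather than
finite-b fits:

* D̄ = Σ_c w_c D_c, with FA/MD/AD/RD from its eigenvalues;
* W = (3/MD²)·sym(Σ_c w_c D_c⊗D_c − D̄⊗D̄), the exact second cumulant of
  the compartment-tensor distribution, fully symmetrized;
* K(g) = MD²·W(g)/D(g)²; MK averages K over the 724-vertex grid, AK is K
  along the principal eigenvector, RK averages K over 64 equispaced
  directions in the perpendicular plane (deterministic), KFA is
  ‖W − W_iso‖_F/‖W‖_F.

NDI is the intra-axonal share of the WM compartment (the NODDI convention),
ODI of a multi-fiber voxel is the fiber-weight-weighted mean of the
per-fiber ODIs, FW is read off directly, and (WM, GM, CSF) fractions form
the fuzzy segmentation. Peaks are the fiber axes ordered by descending
weight, zero-padded to three, and suppressed when the matched WM fraction is
below the reporting threshold (default 0.5; 0.3 is appropriate for
low-resolution data with heavy partial volume). Kurtosis is undefined
(missing value) at MD = 0.

Accuracy of the low-b consistency between the mixture signal and
exp(−b gᵀD̄g): the leading correction is the second cumulant
(b²/2)·Var_c(D(g)), which reaches a few 10⁻³ at b = 100 s/mm² for strong
mixtures — the agreement is second-order in b, not uniformly better than
10⁻³.

## Degeneracy measures

From each voxel's K penalized similarities: uncertainty is the
interquartile range (linear-interpolation percentiles), ambiguity is the
fraction of values strictly above half the maximum. Ambiguity lies in
[1/K, 1] — its floor is 1/K by construction, attained exactly when only the
maximum clears half-maximum. Both are computed on *penalized* similarities
and are undefined (missing) for K < 2 (uncertainty) or a non-positive peak
(ambiguity).

## Synthetic benchmarks

The crossing phantom simulates two-fiber voxels, equally many in each of
eight crossing-angle bins (10–20° … 80–90°), at b = 2000 s/mm² with 150
directions and one b0. Each voxel is pure WM with equal fiber weights,
per-fiber ODI uniform on [0.01, 0.30], in vivo diffusivity priors, and a
uniformly random global rotation; Rician noise (σ = S0/SNR, S0 = 1) is
applied at SNR 50, 20, 10 by default. A crossing counts as resolved when
the matched entry reports exactly two peaks and each is within 20° of its
optimally assigned true axis (over- and under-calling both fail — the
strictest reading consistent with scoring both peak detection and count).

The fiber-count companion draws pure-WM voxels with 1–3 fibers at
continuous (off-grid) random orientations — two-fiber crossings uniform on
[10°, 90°], three-fiber sets with ≥ 10° pairwise folded separation — with
prior-drawn weights and dispersions, and scores the confusion between true
and estimated counts. Because the top-K neighborhood is ranked by
unpenalized cosine, the penalty sweep (α ∈ {0, 10⁻⁵, 10⁻³}) is re-scored
exactly from a single matching pass.

What the phantom emulates and what it does not: it shares the forward
model's compartments and priors (so matching errors reflect noise,
discretization and prior coverage, not model mismatch), uses continuous
off-grid orientations (so the grid's angular quantization is genuinely
exercised), but contains no spatial structure, no partial-volume mixing
across voxels, no eddy/motion artifacts, and Gaussian-channel Rician noise
only. Passing it demonstrates correct recovery under the model's own
assumptions, not robustness to real-world acquisition effects.

## Numerical choices and degenerate inputs

* Bingham densities are computed with a max-shifted exponent (stable at
  κ up to 10⁵); κ(ODI = 1) evaluates to ~6×10⁻¹⁷ rather than exactly 0,
  which is harmless downstream.
* The dispersed-stick average converges to the pure stick as ODI → 0, but
  slowly: at κ = 63.7 (ODI = 0.01) the perpendicular-direction deviation is
  ≈ b·D∥/(2κ) ≈ 0.04 at b = 2000 s/mm²; on the discrete grid the deviation
  falls below 10⁻³ only once the density collapses onto the axis vertex
  (κ ≳ 2×10³).
* Ties everywhere (top-K boundary, penalized selection) are broken
  deterministically (lower index, fewer fibers first) for reproducibility.
* Gradient vectors are renormalized on read; a zero vector on a weighted
  volume is an error, on a b0 volume it is expected.
* Dictionary builds refuse to allocate beyond a configurable memory budget;
  loading a dictionary whose gradient-table fingerprint does not match the
  data's acquisition is refused at fit time.

## Known limitations

* No exchange, soma, or time-dependent compartments; no fiber-radius
  modeling (the intra-axonal radial diffusivity is exactly zero).
* The discrete orientation grid bounds achievable angular precision; axes
  are reported on grid vertices.
* Random sampling leaves the parameter space non-exhaustively covered;
  distinct configurations can be near-degenerate in signal space — this is
  surfaced by the uncertainty/ambiguity maps rather than suppressed.
* Matching is exhaustive per voxel (no approximate search); runtime scales
  linearly in masked voxels × dictionary size.
* No spatial regularization: voxels are independent by design.
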