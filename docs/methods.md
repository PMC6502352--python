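# Methods

## Model

A protein trait is additive: `T(α) = Σ_l Δ_l(α_l)` with the reference
state at each site contributing zero.  Selection acts on a nonlinear
function of `T`, weighting sequences by a Boltzmann factor
`P(α) ∝ exp(w(α))`.  Implemented selection forms:

- **gaussian** — `w = −(κ/2)(T − T*)²`; the default.
- **quartic** — `w = −(κ₄/2)(T − T*)⁴`.
- **rectangular** — `w = 0` for `|T − T*| ≤ h`, weight 0 outside;
  boundary ties are *included*.  The zero-width limit selects exactly the
  sequences whose trait equals `T*`.
- **threshold** — `w = 0` for `T > T_t`, weight 0 otherwise.

Hard-window rejections are represented as fitness `−∞` (a sentinel that
exponentiates to weight exactly 0, never NaN).

Even though `T` is additive, any nonlinear `w` couples sites — global
(nonspecific) epistasis.  The selected ensemble concentrates near the
plane `Σ_l S_l Δ_l = T*`, so `Δ` becomes a direction of anomalously small
variance in sequence space.  That is the signature every detector here
exploits.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| κ | Gaussian selection strength | `10/ΣΔ_l²` (binary) | scales the window with the unselected trait width |
| κ (q-state) | same | `2.5/var(T)` | `ΣΔ²` no longer tracks the trait variance once each site has q−1 non-reference states; for binary sequences `var(T) = ΣΔ²/4`, so this is the same prescription expressed through the unselected variance, and it reduces to `10/ΣΔ²` exactly at q = 2 |
| κ₄ | quartic strength | `κ²/2` | puts the e-fold half-width of `exp(−κ₄x⁴/2)` at the gaussian default's `x = √(2/κ)` |
| γ | relative selection bias | — | `(T* − ⟨T⟩)/std(T)` under the *unselected* ensemble (uniform states, independent sites); recomputable from the spec and recomputed on `resolve()` |
| Λ | pseudocount | 0 raw / 0.01 synthetic spectra / 0.02 for 21-state alignments | mixes frequencies toward uniform before the covariance is inverted |
| ε | spring weakening per mutation | 0.2 | the elastic-network perturbation size |
| d_c | elastic-network cutoff | 7.5 Å | standard Cα/Cβ network construction |

## Elastic-network trait

Each residue contributes its Cα and (except glycine) Cβ; every carbon
pair within `d_c` in the *reference* structure gets a harmonic spring
(constants: backbone-adjacent Cα–Cα 2, other Cα–Cα 1, Cα–Cβ 1, Cβ–Cβ
0.5).  The deformation `δr` is the Kabsch-superposed displacement from a
second conformation; its energy is `E = ½ δrᵀ M δr` with `M` the spring
Hessian.  A mutation at residue `l` multiplies every spring on its Cβ by
`(1 − ε)`; the first-order energy change

    Δ_l = −ε · Σ_{springs s on Cβ_l} ½ k_s (d̂_s · δr_rel,s)²

is non-positive by construction and defines the effect vector.

Because `δr` is held fixed, `E` is *linear* in the spring constants:
single-mutant effects are exact (not just first order), double mutants
are exactly additive unless the two Cβs share a spring, and a shared
spring contributes exactly the `ε² k (d̂·δr_rel)²/2` cross term from
`(1−ε)²`.  The tests assert these exact identities rather than the
looser `O(ε²)` bounds they imply.

Glycine (no Cβ) cannot be "mutated": its `Δ_l = 0`, logged as a warning.
The cutoff is evaluated on the reference structure only; the second
structure enters only through `δr`.  Residues are matched by chain +
author residue number + insertion code; altLocs resolve to the
highest-occupancy conformer.

## Ensembles

- **Enumeration** — all `2^L` binary sequences with exact Boltzmann
  weights; guarded at `L ≤ 20`.  Serves as the oracle for the samplers.
- **Importance sampling** — uniform random sequences reweighted by
  `exp(w)`; this directly mirrors generating unselected sequences and
  weighting them through the selection window.  Effective sample size
  `ESS = 1/Σw²` is recorded, with a provenance warning below 50.
- **MCMC** — Metropolis single-site flips with incremental trait updates;
  burn-in 10·L sweeps, thinning L flips (defaults, logged).  Used where
  extreme selection bias would starve the importance weights.

The weighted covariance is the plain weighted second central moment
(`C_ll′ = ⟨S_l S_l′⟩* − ⟨S_l⟩*⟨S_l′⟩*`) with no small-sample bias
correction, matching the ensemble-average definition.  The pseudocount
mixes single frequencies with 1/2 and pair frequencies with 1/4 (their
independent-uniform values) before the covariance is formed; the q-state
version mixes with `1/q` and `1/q²` on single and pair frequencies, the
standard regularization in inverse-covariance sequence analysis.

## Detectors

- **PCA** — eigendecomposition of `C`, descending; the sector estimate of
  interest is the *last* PC.  Deterministic sign convention:
  largest-magnitude component positive.
- **ICOD** — invert `C` (pseudocount required if singular; the error
  message says so), zero the diagonal, take the *first* eigenvector.
- **SCA** — `C̃_ll′ = |φ_l C_ll′ φ_l′|` with the binary positional weight
  `φ_l = |ln[P_l(1−q̄)/((1−P_l)q̄)]|` (background mutant frequency q̄ =
  0.5 for synthetic data).  For Recovery comparisons the square root of
  the first eigenvector's components is used.  SCA needs conservation to
  work; at zero selection bias it has none and collapses to the random
  baseline — the tests assert this contrast.
- **Recovery** — `Σ|ν_l Δ_l|/(‖ν‖‖Δ‖)`; blind to rescaling and per-site
  sign flips; equals 1 iff `|ν| ∝ |Δ|`.  The random baseline is the
  Monte-Carlo mean over unit vectors uniform on the sphere (10⁴ draws by
  default), with the large-L closed form `√(2/(πL))·Σ|Δ|/‖Δ‖` reported
  alongside.

### ICA step for multiple traits

When N traits are selected at comparable strength, the ICOD spectrum has
N outlier eigenvalues whose eigenvectors mix the effect vectors (with the
default κ each outer product `κ_i Δ_i Δ_iᵀ` has the *same* leading
eigenvalue `κ_i‖Δ_i‖² = 10`, so the outlier subspace is
near-degenerate and the eigenbasis within it is arbitrary).  The
components are un-mixed by rotating the top eigenvectors to maximize
non-Gaussianity of their site profiles: the centered, whitened component
columns are optimized by Jacobi sweeps over column pairs, each pair
rotated to the angle (found by exhaustive grid + local refinement, so the
procedure is deterministic) maximizing the summed squared excess
kurtosis.  The final transform is applied to the *uncentered*
eigenvectors, which restores each separated source's mean offset exactly
when the mixture lies in the eigenvector span.  A fixed-point ICA with
standard contrast functions was evaluated for this step and converged to
non-separating solutions on exactly the sector-sparse sources this
package produces, which is why the rotation search is explicit.

The number of components defaults to the eigenvalue outlier count
(values above median + 6·MAD of the spectrum).

## 21-state extension

Alignments over 20 amino acids + gap are encoded one-hot over the q−1
non-gauge states per site (gauge = per-site consensus by default, ties
broken by state order with the gap first and amino acids alphabetical, or
a given reference).  Columns with gap frequency above 15% are removed
first and never re-enter downstream indexing (every output carries the
retained-site map).  ICOD generalizes by zeroing the (q−1)×(q−1)
*diagonal blocks* of the inverse covariance and compressing each
off-diagonal block to its Frobenius norm, giving a site-level matrix
whose top eigenvector scores overall (not residue-specific) mutational
importance.  Sequence reweighting by identity clustering is off by
default — the synthetic generative model has no phylogeny — and the
per-site conservation score is the KL divergence of observed state
frequencies from a configurable background (uniform by default, so a
fully conserved site scores ln 21 ≈ 3.04).

At q = 2 with the reference gauge the whole construction reduces
algebraically to the binary pipeline (covariance and ICOD matrix equal to
1e-8; tested), except that the Frobenius compression takes absolute
values and therefore legitimately changes the spectrum — comparisons are
made at the last stage where the two pipelines compute the same object.

## Synthetic data

`SectorSpec` draws `n_sector_sites` positions whose effect magnitudes are
uniform in `[0.5, 1.5]·scale_sector` against a background of
`[0.5, 1.5]·scale_background` (default ratio 10), negative by default
(matching the elastic-network trait, where weakening a spring can only
lower a fixed-deformation energy) or with random signs.  Bounded
magnitudes keep the sector strictly separated from the background at the
default ratio, so "the top-|Δ| sites are the sector" holds
deterministically; a heavy-tailed recipe would blur that boundary and is
deliberately not the default.  Sector pairs share
`round(overlap·n)` sites with independently drawn values; q-state effect
matrices put the sector structure in the per-site norm across states.

What the generator does *not* emulate: phylogenetic correlations between
sequences, alignment errors, non-uniform amino-acid usage, and pairwise
(specific) epistasis.  Passing tests therefore demonstrate the method's
behavior under its own generative model, not performance on natural
alignments, where conservation, phylogeny and contacts add structure the
model excludes.

## Numerical choices

- Covariance matrices with condition number above 1e12 are rejected with
  a pseudocount hint rather than silently inverted.
- Eigen-solvers are symmetric (`eigh`) on explicitly symmetrized input;
  eigenvector sign fixed by the largest-magnitude component.
- Problem sizes in the test suite (L = 50–100, 10⁵ weighted samples, 10
  seeds for averaged claims; L = 20, q = 21, ~6·10⁴ samples for the
  multistate checks) were chosen so every simulation-based claim is
  resolved well beyond its tolerance while the whole suite runs in a few
  minutes.
- Known limitation: full site *rankings* from q-state ICOD are only
  determined down to the noise floor — background sites with
  near-identical true scores order arbitrarily, so robustness claims are
  asserted on sector identification and score correlation, not on exact
  rank order.
- MCMC chains assume single-site flips can reach all relevant sequences;
  for zero-width rectangular windows use enumeration instead (the
  sampler cannot move inside a measure-zero set).
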