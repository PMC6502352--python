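# icod — functional protein sector detection from sequence covariance

Groups of collectively coevolving amino-acid positions — *sectors* — show
up in large protein-family alignments and often correspond to a shared
functional role.  This package implements a physical model of how such
sectors arise, and a principled method to detect them.

The model: a scalar protein trait is **additive**,

    T(α) = Σ_l Δ_l(α_l),        Δ_l(α_l⁰) = 0,

where Δ is the per-site mutational-effect vector, and natural selection
acts on a *nonlinear* function of T, e.g. a Gaussian window

    w(α) = −(κ/2) (T(α) − T*)²,   P(α) ∝ exp(w(α)).

Although the trait carries no pairwise terms, the nonlinear selection
couples sites (global epistasis) and confines the selected sequences near
a plane perpendicular to Δ.  The effect vector therefore appears as a
*small-variance* mode of the sequence covariance matrix C.  The **ICOD**
(Inverse Covariance Off-Diagonal) method reads it back robustly: in the
small-coupling regime

    (C⁻¹)_ll′ ≈ (1 − δ_ll′) κ Δ_l Δ_l′ + δ_ll′ (1/P_l + 1/(1 − P_l)),

so inverting C, zeroing the conservation-dominated diagonal, and taking
the **first** eigenvector of the result recovers Δ even when strong
conservation breaks plain PCA.  Agreement between an inferred mode ν and
the true effect vector is scored by

    Recovery = Σ_l |ν_l Δ_l| / (‖ν‖ ‖Δ‖) ∈ [0, 1].

The package provides:

- `icod.trait_models` — additive traits; Gaussian, quartic, rectangular
  and threshold selection; Boltzmann weights; single- and multi-trait.
- `icod.elastic_network` — a Cα/Cβ elastic-network model that turns a
  protein conformational change into a concrete additive trait (the
  deformation energy), with mutations as spring-weakening perturbations.
- `icod.ensembles` — exact enumeration, importance sampling and
  Metropolis MCMC of selected sequence ensembles; weighted covariance.
- `icod.spectral` — PCA, ICOD, the SCA comparator, an ICA step that
  disentangles several simultaneously selected traits, and the Recovery
  statistic with its random baseline.
- `icod.multistate` — the 21-state (20 amino acids + gap) extension:
  one-hot encoding with gauge choice, pseudocounts, gap filtering, and
  Frobenius compression of the ICOD matrix to per-site scores.
- `icod.synthetic` — sector-structured synthetic effect vectors and toy
  structures so the whole pipeline is testable without downloads.

## Worked example

Generate a synthetic sector (L = 100 sites, 20 of them with ten-fold
larger mutational effects), select 10⁵ sequences through an unbiased
Gaussian window, and run all three detectors:

```bash
icod pipeline --seed 0 --out demo_run
```

```json
{
  "config_hash": "2831c2f9abceddb0",
  "gamma": 0.0,
  "kappa": 0.0043712073023749,
  "ess": 69647.96532984234,
  "recovery_pca_first": 0.699497038370883,
  "recovery_pca_last": 0.9996993290739962,
  "recovery_icod_first": 0.9993022601667513,
  "recovery_sca_first": 0.23308653276980415,
  "recovery_random_expectation": 0.4804926935483264,
  "n_icod_outliers": 1
}
```

Reading the numbers: the importance sampler kept an effective sample size
of ~70 000 of the 100 000 draws; the *last* principal component of C and
the *first* ICOD eigenvector both recover the planted effect vector
almost perfectly (Recovery ≈ 0.999, against a random baseline of 0.48),
while conservation-based SCA collapses below the baseline because
unbiased selection produces no conservation signal for it to use.  The
single dominant ICOD eigenvalue (`n_icod_outliers: 1`) correctly reports
one selected trait.

The same workflow is available step by step (`icod synth-delta`,
`icod sample`, `icod cov`, `icod icod`, `icod recover`), from Python via
the functions above, for real structure pairs via `icod enm-delta
--pdb-free free.pdb --pdb-bound bound.pdb`, and for 21-state alignments
via `icod icod21 --msa aln.fasta --pseudocount 0.02 --gap-threshold 0.15`.

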