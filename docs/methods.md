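# Methods

This note documents the statistical conventions behind each stage, the
parameters that matter, and what the simulation-based tests do and do not
demonstrate.

## Data model

A dataset is a samples × loci matrix over {0, 1, missing} with one
population label per sample and a locus → primer map.  Dominant markers
expose only band presence; all statistics start from the band frequency
p = (band-present scores) / (non-missing scores), computed per population or
pooled.  Missing scores (absent from the emulated survey, supported for
robustness) are handled by pairwise deletion: frequencies use non-missing
scores only, and inter-individual mismatch counts over shared loci are
rescaled by n_loci / n_shared.

Two allele-frequency conventions are first-class because the common desktop
packages disagree for dominant data and the reference survey reports both
side by side (GenAlEx H_e vs POPGene h′):

* **band_state** (default): the two phenotypes are the states, (p, 1−p).
* **dominant_hwe**: diploid HWE with a recessive null allele, q̂ = √(1−p),
  optionally with the Lynch–Milligan small-sample correction
  q̂ = √x/(1 − Var(x)/(8x²)), x = 1−p, Var(x) = x(1−x)/N.  The reported
  h′ is gene diversity under this model.  The exact estimator behind the
  published h′ values is not documented by its software, so dominant_hwe/√
  is this package's stated stand-in.

## Marker informativeness

Per locus: PIC = 2p(1−p) (two-state form of 1−Σp_i², max 0.5),
I_b = 1−2|0.5−p|, H = −p ln p −(1−p) ln(1−p) (natural log).  Per primer:
PIC and H′ are unweighted means over all scored bands; RP = Σ I_b;
MRP = RP/PB; MI = PIC × EMR with **EMR defined as the polymorphic-band
count PB** — the only reading that reproduces every published MI cell from
its printed PIC and PB (e.g. 0.42 × 19 = 8.0).  A locus is polymorphic iff
0 < p < 1 pooled (strict criterion; a 95%-rule option exists but is off by
default).  The primer table reports Pearson correlations between the (PIC,
MI) and (PIC, RP) columns as both r and r²; note that published values of
"r²" for such tables are sometimes the correlation coefficient itself —
both are provided so either can be compared.

## Within-population diversity

Per locus with state frequencies (f₁, f₂): N_a = #{states present},
N_e = 1/Σf², I = −Σ f ln f, H_e = 1−Σf², uH_e = H_e · 2N/(2N−1).  The
2N/(2N−1) factor (2N gene copies in N diploids) is the convention that
reproduces published H_e → uH_e pairs (40/39 at N = 20).  Population
summaries are unweighted means over **all** loci, monomorphic ones included
— dropping them would inflate every mean.  %P applies the strict criterion
within the population.

## AMOVA

Distance: band-mismatch count, the squared Euclidean distance on 0/1
profiles and the RFLP/AFLP convention of desktop AMOVA tools.  One-level
decomposition via the squared-distance identity SS = (1/n)Σ_{i<j} d²:
df = (K−1, N−K), σ²_within = SS_w/df_w,
σ²_among = (SS_a/df_a − σ²_w)/n₀ with n₀ = (N − Σn_k²/N)/(K−1), and
Φ_ST = σ²_a/(σ²_a+σ²_b).  Significance: permute individuals among
populations holding sizes fixed (default 10 100 permutations, the reference
survey's setting); the observed statistic is counted in the tail, so
p ≥ 1/(n_perm+1) and p = 0 is never reported.  Negative among-population
components are reported as-is and flagged (clamping is opt-in).  Pairwise
Φ_ST entries are two-population AMOVAs on the corresponding sub-matrix.

## Differentiation and distances

Nei partition with **unweighted** population means (equal pop weights, the
POPGene convention; size-weighting is a flag): per locus h_k = 1−Σf²,
H_S = mean_k h_k, H_T = 1−Σf̄² with f̄ the unweighted mean state frequency;
G_ST = (H_T−H_S)/H_T, G′_ST = G_ST(K−1+H_S)/[(K−1)(1−H_S)],
D = [(H_T−H_S)/(1−H_S)]·K/(K−1).  Gene flow N_M = ¼(1/F_ST−1) under the
island model, computed from the AMOVA Φ_ST when available (the pairing used
by the reference survey: F_ST = 0.221 → N_M ≈ 0.88), else from G_ST.
Nei's (1972) standard distance D_s = −ln[J_xy/√(J_x J_y)] on the chosen
state frequencies (the 1978 small-sample correction is deliberately not
used; the published binary-data pipeline is unspecified).  Slatkin's
F_ST/(1−F_ST) linearizes a pairwise matrix for IBD work; entries at
F_ST = 1 become missing.

## PCoA and the Mantel test

Classical (Torgerson/Gower) PCoA with two centering dialects, because tools
differ on whether the input matrix holds distances or squared distances:
`gower_squared` (B = −½J(D∘D)J, library default) and `gower_raw`
(B = −½JDJ).  For ordinations of pairwise-F_ST matrices the raw dialect is
canonical here: it reproduces the reference survey's published axis
percentages (43.61/26.61/15.08) to 0.1, while the squared dialect does not.
Axis percentages are shares of the positive-eigenvalue total; negative
eigenvalues (non-Euclidean input) are excluded from the denominator.

Mantel: Pearson correlation of vectorized upper triangles; one-tailed upper
permutation test (rows and columns of the second matrix permuted jointly,
observed included; default 10 000 permutations).  Geographic distances are
haversine great-circle km between population centroids (arithmetic mean of
member coordinates, WGS84 decimal degrees, Earth radius 6371.0088 km); no
map projection is needed at the ~100 km scale involved.  Population-level
(K×K) matrices are used, consistent with deriving the genetic side from
pairwise F_ST.

## Admixture model

The no-LD admixture model on haploid band loci: q_i ~ Dirichlet(α…α),
Z_il | q_i categorical, X_il | Z_il=k ~ Bernoulli(F_kl),
F_kl ~ Beta(λ1, λ2) independently.  Haploid coding keeps full conjugacy and
is the common convention for dominant data; the correlated-frequencies
F-model is simplified to independent Beta(1,1) priors (this changes prior
shrinkage only, and all recovery guarantees here are simulation-based).
Defaults: α = 1, λ = (1,1), burn-in 1 000, 100 000 kept iterations, 10 runs
per K over K = 1…10 — the reference survey's settings; tests use
desk-scale chains (hundreds–thousands of iterations).

The Gibbs sweep is Z → F → q with all-conjugate updates.  Per iteration the
observed-data log-likelihood ln P(X|Q,F) is recorded;
ln P(X|K) ≈ mean(lnL) − var(lnL)/2 over kept iterations (the STRUCTURE
summary).  This quantity systematically exceeds the exact marginal
likelihood — at K = 1, where ln P(X) is available in closed form as a
product of Beta-Bernoulli marginals, the gap equals the posterior-prior KL
divergence.  It is retained because Evanno's ΔK (the model-selection rule
used downstream) is defined on exactly this summary:
L′(K) = mean lnP(K) − mean lnP(K−1), |L″(K)| = mean over runs of
|lnP_r(K−1) − 2lnP_r(K) + lnP_r(K+1)|, ΔK = |L″(K)|/sd_runs(lnP(K)),
suggested K = argmax.  ΔK is undefined at the boundary K values and where
the across-run sd is 0.  Short chains occasionally stick in a local mode;
replicate runs per K with selection by lnL (standard practice) are used
wherever a single fit is consumed.  Cluster labels are arbitrary: all
comparisons align by the best label permutation first.

## Synthetic data

The generator is for estimator validation, not biological realism.  Per
locus an ancestral band frequency p_l ~ Uniform(0.1, 0.9); per population
p_kl ~ Beta(p_l(1−F_k)/F_k, (1−p_l)(1−F_k)/F_k) (Balding–Nichols), so
E p_kl = p_l and Var p_kl = F_k p_l(1−p_l).  Bands are emitted haploid
(probability p_kl) or as dominant-diploid phenotypes (1−(1−p_kl)², under
which the √ estimator is exactly consistent).  Optional per-population
admixture mixes population frequencies before emission; coordinates scatter
isotropically around centroids.  For haploid emission the AMOVA Φ_ST
estimand equals the realized variance ratio
Σ_l Var_k(p_kl) / Σ_l [Var_k(p_kl) + mean_k p_kl(1−p_kl)], which the truth
record exposes for exact recovery checks.

The survey preset: 6 populations of 20/20/20/25/10/13, 195 loci partitioned
into the survey's 16 per-primer band counts, F = 0.25, and 28/195 loci
fixed present (the survey's monomorphic bands).  With these settings the
emitted matrices show ~86 % polymorphic bands and Φ_ST ≈ 0.25, inside the
calibration envelope (PPB 80–95 %, Φ_ST 0.15–0.30) the tests assert over
20 seeds.  Centroids are synthetic Kuwait-like coordinates spanning
~100 km.  What the generator does **not** emulate: linkage between bands of
one primer, scoring error, band-size homoplasy, and the survey's
per-population diversity gradient (a per-population F vector can induce
one, but the preset uses a scalar F).  Passing tests therefore demonstrate
estimator correctness under the F-model, not fidelity to any particular
field dataset.

## Numerical and design notes

* 0·ln 0 := 0 throughout; band frequencies validated to [0, 1].
* Permutation p-values always include the observed arrangement; fixed seeds
  make every stochastic result bit-reproducible, and the pipeline spawns
  per-stage child seeds from the master seed in a fixed order (recorded in
  the manifest).
* Sampler experiment sizes in the tests (e.g. 3 × 15 samples × 200 loci,
  chains of ~1 800 sweeps, best of 3 restarts) were chosen as the smallest
  designs that meet the documented separation condition (≥ 50 loci with
  |Δfreq| ≥ 0.6 per cluster pair) with comfortable margin.
* Mantel calibration experiments use 7-point matrices with 199 permutations:
  with 6 points and 99 draws from only 720 distinct permutations, ties with
  the observed statistic make the test visibly conservative.
* Degenerate inputs: all-monomorphic data make G_ST undefined (error);
  F_ST ≤ 0 makes N_M undefined (NaN with warning); I = 0 genetic identity
  makes D_s infinite (NaN with warning); constant distance matrices make
  Mantel r undefined (error).

## Known limitations

* No hierarchical (among-group) AMOVA; no partial Mantel; no bootstrap CIs
  on differentiation indices; no Zhivotovsky Bayesian frequency estimation.
* The admixture sampler does not implement the correlated-frequencies
  F-model or LOCPRIOR/usepopinfo ancestry modes; per-population membership
  summaries are computed post hoc from Q.
* Published G_ST/G′_ST/D triples from mixed software pipelines are not
  expected to be jointly reproducible under any single (H_T, H_S, K)
  convention; only their qualitative behaviour is asserted.
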