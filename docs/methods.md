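# Methods

## The selection problem and the model

The package targets class-labelled expression matrices with tens of
samples and 10³–10⁴ genes, where the goal is a subset of D ≈ 3–13
genes that discriminates the classes. It combines three filter stages
(cheap, classifier-free or classifier-light) with one wrapper stage
(classifier-in-the-loop search), so the expensive search only ever
runs over a 40-gene pool.

### Per-gene separability (stage 1)

The information index to classification sums, over every ordered pair
of classes (j, k),

    ½·|μ_j − μ_k|/(σ_j + σ_k)  +  ½·ln((σ_j² + σ_k²)/(2σ_jσ_k)).

The first term is a standardized mean separation, the second a
dispersion-mismatch penalty that is zero iff σ_j = σ_k. The double sum
is implemented literally over ordered pairs — each unordered pair
counts twice — so multi-class values match the printed formula rather
than a halved variant. Both terms are invariant under positive affine
rescaling of a gene's values (property-tested), which is why the
statistic needs no prior normalization. Per-class standard deviations
use ddof = 1 and are floored at max(10⁻⁶·global σ, 10⁻¹²) so genes
constant within a class stay finite (with a warning); per-class
statistics are computed on the training split only.

### ELM fitness (stages 2 and 4)

The fitness classifier is an extreme learning machine: input weights
and biases drawn once from Uniform[−1, 1], logistic-sigmoid
activation, 0/1 one-hot targets, and output weights solved as the
minimum-norm least-squares solution of H·w_o = T via a rank-revealing
pseudoinverse (singular values below 10⁻¹⁰·s_max truncated; in
production this is `numpy.linalg.lstsq`, and the test suite checks it
against an explicit SVD pseudoinverse written independently). Argmax
decodes the output neurons; exact ties go to the lowest class index.

Hidden-layer size N_H defaults to min(n_train, 20) and is deliberately
config-exposed rather than buried: the source method never reports it,
and it is the single most influential free parameter of the fitness
(see Limitations). Cross-validation is stratified by dealing each
class's shuffled samples round-robin into k folds; a class with fewer
than k samples is simply absent from some folds, which is flagged in
the result rather than being an error — small-class datasets (e.g. a
6-sample class in a 5-class study) must still be evaluable.

### Subset screening and gene scoring (stages 2–3)

By default 20·|pool₁| random subsets with sizes uniform on [5, 15] are
drawn from the 300-gene first-level pool (sizes bracket the 3–13-gene
subsets such methods typically report). Each is scored by 5-fold CV
accuracy under one shared fold assignment (comparability across
subsets); subsets below θ_ac = 0.80 are deleted. Zero survivors is a
loud error telling the user to lower θ_ac. Survivors are ranked 1..l_se
by accuracy, ties broken by smaller subset then draw order.

The scoring rule — raw score of gene i = Σ (l_se − R_j + 1) over
surviving subsets j containing i — is a reconstruction: membership
weighted by reversed rank, using exactly the available ingredients
(survivor ranks). It is pluggable (any callable over ranks) so
alternatives such as Σ 1/R_j are one-line swaps. Min-max normalization
maps member genes onto [0, 1] (degenerate case: all ties map to 1.0);
non-members score 0. The top 40 scorers form the third-level pool,
ties broken by higher separability, then lower index.

### Annealed swarm (stage 4)

Particles are D continuous coordinates over pool slots; decoding
rounds, clamps to [0, |pool|−1], and repairs duplicate slots by
advancing cyclically to the nearest unused slot, so every particle is
always a valid D-gene subset while the velocity/position algebra stays
exactly the textbook inertia-weighted PSO. Velocities are clamped at
v_max = |pool|/2. Both schedules (inertia 0.9 → 0.4, temperature
T₀ = 0.1 → T_end = 0.001) decrease linearly and are computed in
interpolation form a·(1 − t/It_max) + b·(t/It_max), which is
endpoint-exact in floating point.

The swarm best p_g is updated per particle through the Metropolis
rule: accept when the candidate is better by ≥ ε (ε = 0.01 on the
accuracy scale); accept with probability exp(−|Δf|/T) when within ε;
reject when worse by ≥ ε (the rejection branch is the only reading
consistent with p_g being a "best" position). Because this can move
p_g to a marginally worse position, the best subset ever evaluated is
tracked separately and greedily; it is the reported result, its
fitness is non-decreasing by construction (assertable on the trace),
and stagnation is measured against it. After N_mu = 3 stagnant
generations, a uniformly chosen half of the swarm is reinitialized
(positions, velocities and personal bests), leaving p_g and the best
-ever record untouched.

Metropolis coin flips consume a dedicated RNG stream, separate from
the swarm-dynamics stream. This makes the greedy limit exact: as
T → 0⁺ and ε → 0⁺ the acceptance decisions coincide with
accept-iff-not-worse, and the annealed trajectory becomes bit
-identical to the greedy baseline on shared seeds — a strong
regression guard on the whole update path. Fitness evaluations are
memoized per subset within a run, and the CV fold assignment is fixed
per run, so a subset's fitness is stable and stagnation is well
defined. The plain-PSO baseline (`IPSOConfig.standard_pso()`) is the
same optimizer with greedy p_g updates and mutation disabled.

## Pipeline protocol

The train/test split (default fraction 0.65, stratified,
largest-remainder apportionment) is drawn once per run; all repeats
share it, and vary only in stage seeds — mirroring the
repeated-trials protocol under which such methods report mean
accuracies and selection frequencies. Expression values are z-scored
per gene on the training split (statistics frozen and applied to the
held-out rows) before any ELM sees them; raw intensities saturate a
sigmoid hidden layer. Stages 1–4 receive only training rows; the
held-out rows are touched exactly once per repeat, by the final ELM
trained on the full training split (a poisoning test asserts this
hygiene). The master seed fans out through named `SeedSequence`
children, so any single repeat is reproducible in isolation and a
whole run serializes to a byte-identical JSON report.

## The synthetic generator

`generate` plants k informative genes whose class means are spaced
δ·σ apart (class j shifted by (j−1)·δ·σ) among independent
Normal(0, σ²) noise genes; truth positions are shuffled so positional
bugs surface in recovery tests. A log-normal toggle exponentiates the
field for skewed positive intensities. What it deliberately lacks:
gene–gene correlation, probe/batch effects, heavy-tailed noise.
Passing recovery tests therefore demonstrate the machinery finds
planted univariate signal; they do not certify performance on real
arrays with correlated genes and artifacts.

`deceptive_landscape` additionally plants decoy gene sets carrying
class signal on only ~80% of samples, with a fixed ~15% "hard core"
of samples no decoy explains — decoy-only subsets plateau strictly
below the truth set's fitness, creating the local optima that motivate
the Metropolis updates and half-swarm mutation.

## Problem sizes used in tests and the acceptance script

Recovery experiments run at 60 samples × 2,000 genes with 10 planted
genes at δ = 2 (20 repeats), the deceptive comparison at 60 × 40 with
8 decoy sets over 50 paired seeds, and the remaining checks on
problems of at most a few hundred genes — sizes chosen so the full
suite completes in minutes on one CPU while still exercising every
stage at realistic shapes.

## Known limitations

- **Fitness saturation at small n.** With ~40 training samples,
  5-fold CV accuracy takes few distinct values and the search can
  drive it to exactly 1.0 by pairing truly informative genes with
  noise genes that happen to separate the training split. At planted
  effect δ = 2 the measured consequence is that selected 5-gene
  subsets typically contain 3–4 planted genes rather than 5: the
  maximizer of the fitness itself contains chance genes, independent
  of hidden-layer capacity (checked at N_H ∈ {5, 11, 20}). The
  level-3 pool, by contrast, retains all planted genes essentially
  always; the cascade is not the bottleneck. Repeated-run frequency
  tables are the intended remedy: chance genes are split-specific and
  wash out across repeats.
- **N_H and the activation are free parameters.** The method's source
  never reports them; results are sensitive to N_H and it must be
  treated as a tuning knob, not a constant.
- **θ_ac is dataset-dependent** (hence the built-in sweep driver); too
  high a value aborts stage 2 loudly.
- No support for raw array formats, normalization pipelines or batch
  correction: input is a processed, finite expression matrix.
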