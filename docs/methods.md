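# Methods

## The model

`grnattract` treats a small transcription-factor network as a deterministic
ODE system with one mRNA and one protein variable per gene:

    dR_i/dt = V_min,i + (V_max,i − V_min,i) · f_i(P) − D_mRNA,i · R_i
    dP_i/dt = V_trl,i · R_i − D_protein,i · P_i

TF binding and diffusion are assumed instantaneous relative to
transcription and translation; decay and translation are linear.  The
production fraction `f_i ∈ [0, 1]` encodes the discrete architecture
`A_net = {AM, LG}`: each regulator `j` of gene `i` contributes a Hill
occupancy `S(P_j) = P_j^k_i / (P_j^k_i + T_j^k_i)`; activator and repressor
occupancies are aggregated by the gene's two logic-gate flags into a
combinatorial activation term `C_A` (independent: `1 − Π(1 − S)`,
synergistic: `Π S`) and repression term `C_R` (independent: `Π(1 − S)`,
synergistic: `1 − Π S`), and finally

    f = f0 + f0·(C_A − 1)·(1 − C_R) + (1 − f0)·C_A·C_R,

algebraically equal to `f0·(C_A + C_R − 2·C_A·C_R) + C_A·C_R`.  The basal
fraction `f0` is both the unregulated production level and the arbiter when
activation and repression are simultaneously saturated.

**Empty-set conventions.** A gene with no activators has `C_A = 0`; one
with no repressors has `C_R = 1`, regardless of the gate flags.  This is
the unique convention under which an unregulated gene transcribes at
exactly `f0`, and it is consistent with freezing both gate flags to 0 for
genes with fewer than two regulators (where coordination cannot matter).

**Parameter indexing.** The half-occupation abundance `T` is stored per TF
(one value per regulator, estimated from its average expression), with an
optional per-(target, regulator) override matrix for forward simulation.
The Hill coefficient `k` is stored per target gene and shared by all of
that gene's regulators.

**Non-goals.** Explicit protein–protein interactions, stochastic dynamics,
delays and chromatin state are outside the model; protein-level regulation
can only appear indirectly as effective transcriptional edges.

## Numerical integration and attractors

Trajectories use classical fixed-step RK4 with state clipping at zero
(negative abundances are unphysical; stage evaluations clip their inputs so
fractional Hill exponents never see negative values).  A state is declared
a fixed point when the normalized mRNA residual `max_i |dR_i| / max_j I_ij`
stays below `1e−6` for 50 consecutive steps — the same per-gene-max
normalization as the attractor distance, making the criterion scale-free.
A bounded trajectory that fails this by the horizon is classified
oscillatory/non-converged; a non-finite one as diverged.  Both classes draw
the same fixed penalty during inference, since steady-state profiles give
no information with which to score oscillations.

Defaults: the horizon is `25 / min(D)` (about 36 half-lives of the slowest
first-order decay, mRNA or protein — the protein pool is usually the
relaxation bottleneck), and the suggested step is `0.3 / max(D)`, well
inside the RK4 stability region for these production-bounded systems.  The
single-trajectory API defaults to `dt = 1 s`; the search and benchmark
layers use the suggested step.  Both are configurable everywhere.

The **attractor distance** between a simulated endpoint and a profile is
the per-gene-max-normalized mean absolute difference
`(1/n) Σ_i |state_i − I_ij| / max(I_i,*)` — a scaled L1 metric.  Two
attractors are *matched* when their distance is below 0.16, a cutoff
calibrated so that a per-gene uniform null model rarely matches (see
below).  Endpoint deduplication in the global attractor search merges
points closer than 0.01; nearest-profile matching breaks ties toward the
lower profile index.

The **global attractor search** integrates from the Cartesian grid of
per-gene levels (3 levels per gene up to 7 genes, 2 above; grid size capped
at 20,000 states) spanning the observed expression range, and returns the
deduplicated converged endpoints.

**Initial states.** Measured profiles are read as attractors; integration
starts from the profile after adding a uniform perturbation
`U(−power, power) · max(I_i,*)` per gene (default power 0.1), clipping at
zero.  Protein is initialized at its steady-state image
`V_trl · R / D_protein` so initial states are internally consistent with
the steady-state reading.  Knocked-out genes are clamped at `R = 0`,
overexpressed genes at their maximal observed level; a clamped gene's
protein still evolves from the clamped mRNA.

## Parameter estimation

Measured inputs are `V_max`, `V_trl`, `D_mRNA`, `D_protein` (lengths
optional, converting polymerization rates to per-molecule rates once at
load).  The remaining parameters are steady-state inversions:

- `V_min,i = D_mRNA,i · min_j I_ij` (capped at `V_max` with a warning);
- `T_i = V_trl,i · mean_j I_ij / D_protein,i` — absent prior knowledge a
  TF is taken as equally likely on or off, so its threshold sits at the
  protein image of its average expression;
- `k`: assuming the profiles contain fully activated genes, the occupancy
  at each TF's maximal observed protein abundance is set to a saturation
  level (default 0.95, configurable): `k_TF = ln(s/(1−s)) / ln(P_max/T)`,
  falling back to 2 when `P_max ≤ T`.  Per-gene `k` averages the values of
  the gene's regulators when an architecture is available and of all TFs
  otherwise (the evolutionary search needs architecture-independent `k`),
  clipped into [1, 10]; unregulated genes default to 2.
- `f0`: per profile, the implied production fraction
  `f* = (D_mRNA·I − V_min)/(V_max − V_min)` (clipped to [0, 1]) is inverted
  through the regulation function, `f0 = (f* − C_A·C_R)/(C_A + C_R −
  2·C_A·C_R)`, using the profile's steady-state protein levels; profiles
  with `|denominator| ≤ 1e−6` (activation and repression both saturated)
  are unidentifiable and skipped; the estimate is the unweighted mean over
  identifiable profiles.  A gene with no identifiable profile gets 0.5
  flagged invalid; a mean outside [0, 1] is returned unclipped with its
  flag false, so the search can penalize it.

These are deliberately qualitative inversions; all four estimators sit
behind one interface so that independently measured values can be
substituted via a parameter table.  The exact `k` inversion is the least
constrained choice here and is flagged as such.

## The evolutionary search

Defaults: population 100, 800 generations, Hamming step 1 per matrix per
generation, perturbation power 0.1, 30 independent runs, consensus
threshold 0.5.  Per generation:

1. every individual's adjacency matrix mutates in exactly `hamming_step`
   entries (new value uniform over the other two; a ChIP prior multiplies
   the probability of mutating a supported entry to zero by 0.2; sparsity
   mode sends selected nonzero entries to zero with probability 0.8) and
   its gate flags flip likewise among mutable flags, re-freezing flags for
   genes left with fewer than two regulators (this enforcement may change
   additional gate entries; the adjacency step stays exact);
2. `f0` is re-estimated per individual; each gene with `f0 ∉ [0, 1]` adds
   1.0 to that individual's average distance;
3. all individuals integrate from the perturbed profiles (one shared
   perturbation draw per generation) plus auxiliary states: for each
   independent self-activating gene and each profile not already containing
   that gene at its maximum, a copy with the gene raised to its maximum is
   added — such states probe whether the network can silence a
   self-activator, penalizing architectures that are stable everywhere.
   Auxiliary states are scored against the nearest profile, regular states
   against their origin profile; non-converged endpoints score 10.0 (any
   legitimate distance is O(1));
4. the mutated population replaces the incumbent iff its population-minimum
   average distance improves (the acceptance rule operates on the
   population minimum, as specified; a per-individual variant is available
   behind a flag for ablation);
5. every individual accumulates `fitness += 1/max(distance, 1e−6)`
   cumulatively across generations, the population is sorted by fitness,
   and the bottom 20% is replaced by copies of the top 20%.

The **consensus** over independent runs is the fitness-weighted mean of the
fittest architectures' signed adjacency entries, thresholded at 0.5 (entry
= sign of the score where |score| ≥ threshold); gate flags take the
fitness-weighted majority.  Run results depend only on their seeds, never
on execution order.

## Synthetic benchmarks and what they do (not) show

`generate_reference_grn` rejection-samples architectures (self-activation
biased: multistability in this model family lives on independent
self-activating switches) with bacterial-scale kinetic defaults
(transcription 0.05 transcripts/s, mRNA half-life ~4 min, translation
0.06 /mRNA/s, protein half-life ~12 min, `V_min = 0.02·V_max`, `f0` drawn
in [0.03, 0.12], `k` in [4.5, 8], `T` at 40% of the open-loop protein
maximum), keeping the first network whose global search finds at least the
requested number of fixed points (9 by default, mirroring the validation
requirement) with no oscillatory or divergent grid starts.  Two additional
admission conditions enforce the estimation chain's own input assumptions:
each gene's attractor minimum must fall below 30% of its attractor maximum
(the profiles must exercise every gene), and each gene's attractor maximum
must put its protein above 1.25 × its half-occupation abundance (otherwise
near-saturation `k` estimation has nothing to anchor on).

`generate_attractor_profiles` adds i.i.d. Gaussian noise to the attractor
matrix, by default with standard deviation `0.2 × rms(clean matrix)` —
the ~14 dB signal-to-noise regime — clipped at zero; per-gene-max and
absolute scalings are available.

Because these benchmarks are generated by the same ODE family the
inference evaluates, self-consistency results (recovery F1, knockout
matching) are an upper bound on real-data performance; an external data
generator can be substituted by supplying any profile table.  The bundled
fixture suite (five networks at 5–9 genes) is regenerated from fixed seeds
at import time — nothing is stored on disk.

The **null model** draws each gene uniformly between its observed extremes
and reports the probability of landing within the matching cutoff of *any*
input profile.  On the bundled fixtures at cutoff 0.16 this probability is
small for the larger networks but not uniformly below the 5%/2% levels the
cutoff was originally calibrated to: corner-rich attractor sets of coupled
bistable switches, dense attractor counts (the 8-gene fixture has 34 fixed
points) and measurement noise on the stored profiles all inflate it.  The
acceptance suite asserts the original bounds and reports the measured
probabilities; the per-target variant (probability of matching one
*specific* profile) is roughly an order of magnitude smaller.

**Scoring** against a reference topology ranks |consensus score| for
AUROC/AUPRC over edge existence and computes F1 at a score threshold with
sign agreement required for a true positive (a sign-blind mode supports
comparisons against unsigned methods); self-edges can be excluded and
directed scores folded to undirected by the larger absolute score.
Attractor sets across networks are paired greedily by ascending distance
(bijective on the smaller set); an optimal-assignment variant is available.

**Dropout prediction** re-runs the full search without the held-out
genotype, applies the held-out perturbation's clamps to the consensus
network, and integrates from every retained profile (strict mode — the
omitted profile is unavailable at prediction time; an oracle mode starting
from the omitted profile exists for comparison), reporting the reached
attractor nearest the held-out truth, or "no attractor" when nothing
converges.

## Problem sizes and defaults used in the shipped experiments

The packaged tests and the worked examples run at desk scale: 3-gene
ground-truth recovery at population 50 / 300 generations / 5 runs, the
architecture–attractor coupling scan at 100 mutants per Hamming distance
1–10 on the 5-gene fixture, and the null model at 100,000 draws.  These
sizes were chosen to exercise every code path at full fidelity while
keeping each experiment in the minutes range; the search scales to the
default population 100 / 800 generations / 30 runs unchanged.

## Known limitations

- Oscillatory and multi-stable-with-unobserved-attractor regimes are
  penalized, not modeled; time-series data are out of scope.
- The `k` estimator is a principled stand-in (near-saturation anchoring);
  alternative estimates can be supplied directly.
- Identical attractor sets can be produced by distinct architectures;
  the consensus mitigates but cannot remove this degeneracy, which is why
  edge scores and support frequencies are reported alongside the
  thresholded matrix.
- Self-generated benchmarks share the model family with the inference —
  performance numbers on them are optimistic relative to profiles produced
  by an independent simulator or by experiments.
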