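# Methods

This note records the models the package implements, the numerical choices
made where the method leaves room, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Node models and estimation

Every node of a candidate GWGEN is modelled as a static linear relation over
the N samples of one phenotype group. For a protein q with candidate
interactors r = 1..G_q:

    p_q[n] = Σ_r κ_qr · p_q[n] p_r[n] + λ_q + μ_q[n]

The interaction regressor is the *product* of the node's own expression with
the partner's — interaction strength scales with the abundance of both
partners. For a gene x with candidate TF/lncRNA/miRNA regulator sets of
sizes (U_x, V_x, W_x):

    g_x[n] = Σ_u α_xu t_u[n] + Σ_v β_xv l_v[n] − Σ_w γ_xw m_w[n] g_x[n] + λ_x + μ_x[n]

with the same form for lncRNA and miRNA targets. miRNA terms are again
productwise in the target's own expression and carry a sign constraint
(coefficient ≤ 0; equivalently γ ≥ 0): miRNAs act post-transcriptionally as
repressors. The basal level λ is a free intercept absorbing unmodelled
epigenetic effects (methylation, mutation, histone modification); it is not
separately identifiable from those causes and is treated as a single
parameter. μ is environment/measurement noise and is never stored — the
residual is its estimate.

Estimation is least squares with box constraints: the unconstrained
minimum-norm solution is used when it already satisfies the constraints,
otherwise `scipy.optimize.lsq_linear` refines it (BVLS on full-rank
overdetermined designs, trust-region otherwise; solver tolerance 1e-12,
post-hoc clipping of constraint violations below 1e-9). The residual error
is Ω = ‖y − Φθ̂‖²/N — division by N, not by residual degrees of freedom,
matching the order-detection criterion below. Rank-deficient designs return
the minimum-norm solution and set a warning flag; constant regressor columns
are kept. Expression is fitted raw; the loader offers optional per-node
z-scoring, off by default.

A caveat worth stating plainly: the productwise regressors contain the
response's own values, so the noise term appears inside some regressor
columns. The per-sample model equation still holds exactly (the regression
residual *is* μ), but ordinary least squares on such columns is not
unbiased, and the bias grows with the noise-to-signal ratio. At the
generator's default conditions (noise sd 0.1 against basal levels of 2–4)
the bias is small (mean absolute ability error ≈ 0.03); at basal levels
comparable to the noise it would not be.

## Order detection and pruning

Candidate networks mined from interaction databases over-specify each node's
order. The true subset of regulators is chosen by minimizing

    AIC(subset) = log Ω(subset) + 2 (O + 1) / N

where O is the subset size (+1 for the intercept) and Ω the constrained fit's
residual error, floored at 1e-12 before the log so perfect fits stay finite.
The search is exhaustive for nodes with at most `exhaustive_cap` (default 12)
candidates and greedy backward elimination beyond that: start from the full
candidate set, repeatedly remove the regressor whose removal most decreases
AIC, stop when no removal helps. When N is too small to fit the full set the
greedy start is the largest nested model with candidates ranked by absolute
marginal correlation. Ties are broken toward the smaller subset, then
lexicographically by regulator ids — selection is fully deterministic.

Edges outside the selected subsets are pruned. A PPI pair q–r survives if r
is selected in q's fit *or* q in r's fit (each protein's equation is fitted
independently; either detection is evidence for the interaction), and each
surviving direction carries that fit's κ̂. Pruning removes edges only, never
nodes.

Selection behaviour under the 2/N penalty deserves a note: a spurious
*exogenous* regressor decreases AIC exactly when its chi-square improvement
exceeds 2, which happens with probability ≈ 0.16 regardless of N. Spurious
*productwise* regressors (PPI partners, miRNAs) contain the response's noise
and are genuinely correlated with the residual, so spurious PPI partners are
retained far more often, and the OR survival rule doubles their chance
again; spurious miRNA regulators, by contrast, are almost always rejected
because their spurious coefficient lands on the forbidden positive side of
the sign constraint. Realistic false-positive retention for PPI edges is
therefore substantial by construction — a property of the model family, not
of the implementation — and the pruning stage should be read as removing
*unsupported regulations* reliably and unsupported interactions only partly.

## Principal network projection

The real GWGEN's abilities form H with one row per node (protein block
first — TFs and receptors are protein-class — then genes, lncRNAs, miRNAs;
id-sorted within blocks) and one column per potential source (protein
partners/TFs, lncRNAs, miRNAs); absent edges are zeros. From the SVD
H = S·V·Dᵀ, normalized energies E_i = v_i²/Σv² are accumulated until they
reach the threshold (default 0.85); the retained count I is minimal with
cumulative energy ≥ threshold. Node a's projection onto retained right
singular vector b is Z(a,b) = h_a·d_b, and its score is the two-norm
S(a) = sqrt(Σ_b Z²). The summed-squares form (no square root) produces the
identical ranking; the root is taken for the norm interpretation. The core
network is induced on the top `core_size` nodes (default 6000, capped at the
node count), ties at the cutoff broken by node id. Scaling H by c > 0 scales
all scores by c and leaves the core set unchanged.

## DTI classifier

Drugs and targets arrive as numeric descriptor tables (reference sizes: 363
molecular-descriptor features per drug, 996 protein-descriptor features per
target; descriptor computation itself is out of scope). Preprocessing is
fitted on training pairs only: per-feature z-scoring (constant features map
to 0 with a warning; min-max scaling exists as a config option), seeded
undersampling of the majority class to 1:1, and per-block PCA keeping the
minimal leading components whose cumulative explained variance reaches 0.85
per block — per block rather than on the concatenated vector, so drug and
target structure are reduced symmetrically and independently.

The classifier is a feed-forward network, default widths input → 512 → 256 →
128 → 64 → 1, ReLU hidden activations with inverted dropout (rate 0.4) after
each hidden layer, sigmoid output, mean binary cross-entropy loss. The
reference optimizer is plain mini-batch gradient descent θ ← θ − η∇L with
η = 0.003, batch 100, 100 epochs (Adam available via config). Training is
fully seeded (He initialization, shuffling, dropout masks all flow from one
generator); inference disables dropout and is deterministic. Early stopping
monitors validation loss with patience 10 epochs and restores the best
parameters; with dropout and a small learning rate the validation loss can
plateau early, so cross-validation fold scores are typically conservative
relative to a full-budget fit. Five-fold cross-validation uses seeded
disjoint folds that exactly partition the training pairs. A NaN loss aborts
with diagnostics rather than returning a broken model.

Evaluation reports the confusion counts at cutoff 0.5 (the cutoff is a
convention, not part of the model), TPR, specificity, FPR, the ROC curve
swept over all distinct scores, and the trapezoid AUC; a single-class test
set yields an undefined (absent) AUC.

## Drug design specifications

Biomarkers carry a direction: (+) abnormal overexpression, (−) abnormal low
expression in the disease group. A drug is *sign-consistent* for a biomarker
when its regulation ability reverses the dysregulation — negative regulation
for (+), positive for (−); zero regulation reverses nothing. Sign-consistency
is the only hard filter by default: the published screening table selects a
drug whose LD50 is the lowest on the table, so numeric toxicity/sensitivity
cutoffs clearly were not applied there, and they are provided as optional
configuration (an LD50 floor, a sensitivity ceiling) plus ranking keys
instead.

The combination is assembled by greedy set cover: repeatedly pick the drug
covering the most uncovered biomarkers, breaking ties toward the drug
admissible for more biomarkers overall (multi-target economy), then toward
the larger mean |regulation| over newly covered biomarkers, then the lower
(more potent) sensitivity score, then the name. The coverage-breadth
tie-break matters: ranking purely by |regulation| would assemble
single-target drugs with strong individual effects instead of the compact
multi-target combination, and on the bundled OSCC table it is exactly what
reproduces the published three-drug answer. The reported assignments are
all sign-consistent (drug, biomarker) pairs of the selected drugs, so
re-checking them post hoc never fails.

## Synthetic data

The generator produces every fixture the stages assume, always returning the
ground truth alongside the data.

*Networks.* Typed nodes in tiers: TFs, driver lncRNAs/miRNAs and root
proteins are sources; dependent proteins interact with root proteins; genes
and dependent lncRNAs/miRNAs are regulated by TFs and the driver tiers. All
edges point downstream, so dependence is acyclic and expression can be
solved in closed form. miRNA abilities are drawn negative; other abilities
uniform in ±[0.2, 0.8]. Protein interaction abilities are rescaled once at
generation time so |Σ κ p_r| ≤ 0.9 over the whole driver support, keeping
the inversion below well-posed for every draw.

*Expression.* Drivers are uniform(0.5, 1.5) per sample; dependent values
solve their model equation exactly: p = (λ+μ)/(1 − Σκp_r) for proteins,
g = (Σαt + Σβl + λ + μ)/(1 + Σγm) for targets, with i.i.d. Gaussian noise μ
(sd 0.1). Basal levels are uniform(2, 4): a log-intensity scale on which
regulatory effects are perturbations around a substantial baseline, as on
microarray data — and the scale at which refits recover the planted
abilities with mean absolute error well under 0.05 at N = 200. Default
sample count is 200 per phenotype group; a configurable fraction of edge
abilities can be re-drawn for the case group to create group differences.

*Candidate networks.* True edges are binarized and augmented with decoys
sampled uniformly (seeded) from the typing-consistent non-edges; the decoy
list is returned so pruning accuracy can be scored.

*DTI data.* Drug/target descriptors are standard Gaussian; a pair's clean
label is the sign of a hidden unit-norm linear score of the concatenated
vector, pairs scoring within the margin (default 1.0) of zero are discarded,
labels are flipped at the label-noise rate (default 2%), and the
negative:positive ratio is enforced exactly. The hidden rule is returned for
replay checks.

*Drug profiles.* A known minimal covering set of strongly sign-consistent
drugs is planted among distractors that are sign-consistent on at most one
biomarker with small |regulation|.

What the generator does **not** emulate: probe-level effects, batch
structure across studies, heavy-tailed or correlated noise, cyclic
regulation, post-transcriptional effects beyond the miRNA product term, or
realistic descriptor distributions. Passing tests on these fixtures
demonstrate that the estimation, selection, projection and training
machinery behaves as specified under the model's own assumptions — not that
the pipeline is robust to real-data violations of them.

## Problem sizes used in the bundled checks

The self-contained verification runs use a 62-node network (N = 200 per
group) for recovery and energy checks, a ~20-node network with ~30 true and
~30 decoy edges for the pruning check, a 6100-node gene-heavy network for
the core-size rule, 2000 drug–target pairs (363 + 996 descriptors, 200
drugs × 120 targets) for the classifier check, and the 20-row bundled
screening table for drug selection. These sizes exercise every code path at
desk scale; the algorithms are dense-linear-algebra bound and scale to the
tens of thousands of nodes of a genome-wide study through the greedy order
search and the truncated projection path.

## Known limitations

- The implicit protein model gives least squares a built-in endogeneity;
  interaction abilities are consistent only in the low-noise regime the
  generator targets, and false-positive interactions survive pruning at a
  rate no AIC penalty can push below the chi-square tail (see the order
  detection section).
- The AIC subset search is exact only up to the exhaustive cap; greedy
  backward elimination can miss jointly-informative regulator sets.
- The DTI classifier is a generic feed-forward network on precomputed
  descriptors; nothing chemical is learned beyond what the descriptor
  tables encode.
- Pathway annotation (the step downstream of the core network) is out of
  scope; the core-network TSV is the hand-off point.
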