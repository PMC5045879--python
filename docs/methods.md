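# Methods

This note records the statistical models, the numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Differential expression

The design is a balanced one-way layout over T time points with r replicates
each, on log2 expression. For gene g the stage fits per-time means and the
K = T−1 consecutive-time contrasts β̂_gk = x̄_g(t_{k+1}) − x̄_g(t_k), with the
pooled within-time residual variance s²_g on d_g = n − T degrees of freedom
and the unscaled contrast variance v_gk = 1/r_k + 1/r_{k+1}.

Variance moderation assumes the gene-wise variances are exchangeable draws
from a scaled inverse-chi-square prior s²_g ~ s₀²·d₀/χ²_{d₀}. The prior is
estimated by moment matching on z = log s²_g: under the model
E[z] = log s₀² + ψ(d₀/2) − log(d₀/2) + ψ(d_g/2) − log(d_g/2) and
Var[z] = ψ′(d₀/2) + ψ′(d_g/2), so d₀ solves a trigamma equation (inverted by
Newton iteration) and s₀² follows in closed form. When the observed spread
of log-variances is at or below pure sampling noise, d₀ = ∞ and every
posterior variance collapses to s₀² (the F test then uses a χ² reference).
With d₀ forced to 0 the statistics reduce exactly to the classical per-gene
one-way ANOVA, which the tests verify against `scipy.stats.f_oneway`.

The omnibus statistic is F_g = β̂ᵀV⁻¹β̂ / (K·s̃²_g), where V = C·diag(1/r)·Cᵀ
is the contrast covariance factor — the mean of the squared moderated t
values after orthogonalizing the (correlated) consecutive contrasts — with
reference distribution F(K, d₀+d_g). Raw p at α=0.01 is the default DEG
call; Benjamini–Hochberg adjusted mode is available.

Direction calls are made against the t=0 baseline by default (a
"consecutive" mode diffs successive times instead): the filter keeps a gene
as up- (down-) regulated iff its sign profile over non-baseline times holds
≥ `min_run`=2 consecutive positive (negative) signs. A gene qualifying both
ways goes to the direction with the larger |cumulative effect| over its
qualifying run; exact ties are dropped so the up/down query sets stay
disjoint (a requirement of the enrichment scorer).

Normalization is the quantile step only (columns mapped onto the mean
quantile distribution, average-rank ties): inputs are assumed to be already
background-corrected, probe-summarized log2 values. Probe-level processing
of raw array files is deliberately out of scope.

## Gaussian graphical model

With n samples ≪ p genes the sample covariance S is singular, so the stage
uses the analytic shrinkage estimator with the unequal-variance diagonal
target: correlations are shrunk as r* = (1−λ)r with
λ = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r²_ij (clipped to [0,1]), and variances kept
at their unbiased estimates. Σ* is positive definite whenever λ > 0; its
inverse gives the full-order partial correlations
pcor(i,k) = −ω_ik/√(ω_ii·ω_kk), verified against per-pair regression
residualization to 1e−8 and equal to the (shrunken) Pearson correlation in
the two-gene case. Note that on *fully independent* data λ legitimately
approaches (and may clip to) 1: with nothing worth preserving off-diagonal,
full shrinkage is the risk-optimal answer, and every pcor becomes exactly 0.

Edge significance models the observed pcor values as a mixture of a null
component f₀(r;κ) ∝ (1−r²)^((κ−3)/2) — the exact distribution of a partial
correlation under the empty graph, with κ acting as an effective sample
size — and an alternative carried by the tails. κ is fitted by maximizing
the f₀ likelihood truncated to the central 75 % of |pcor| (|R|² ~
Beta(1/2,(κ−1)/2) gives closed-form cdf and normalizer); the null fraction
η₀ is the central count divided by the fitted null mass there, clipped to 1.
Two-sided p-values are the f₀ tail beyond |pcor|, BH-adjusted across pairs.
On identity-precision data with an invertible unshrunk estimate, 2–10 % of
pairs fall below p = 0.05 (checked by simulation); on the shrinkage path the
rate can fall to 0 when λ clips to 1, which errs conservative.

Edge selection ranks unordered pairs by |pcor| and keeps ⌈q·n_pairs⌉ (ties
at the cutoff all kept and logged), or keeps adjusted p < α pairs, or the
intersection. Both signs of association are retained. The network stage
feeds on the DEG-restricted expression matrix with all time × replicate
columns pooled as observations.

## Topology and SV ranking

All centralities treat the network as simple, undirected and unweighted.
Definitions: DC = deg/(n−1); BC = normalized shortest-path betweenness;
CC = (#reachable others)/(Σ distances), per component; EC = 1/eccentricity;
CLC = triangle density of the neighbourhood; BRC = bridging coefficient
(1/deg(v))/Σ_{u∈N(v)} 1/deg(u) times normalized BC; BROC = (1−CLC)·DC;
LAC = mean degree of N(v) inside the subgraph induced by N(v). BRC, BROC
and LAC follow the standard published conventions for those names; they are
reconstructions documented here, not imports of any specific tool's code.
Global metrics average over connected ordered pairs (distance, diameter)
or all ordered pairs with 1/d = 0 for disconnected ones (efficiency).

Parameters are min–max normalized onto [−1,1] for reporting; the map is
monotone, so the SV scheme ranks on raw values and is unaffected by it.
The SV score groups the eight locals into five groups (G1 = DC, G2 = BC,
G3 = BRC, G4 = {CC, EC}, G5 = {CLC, BROC, LAC}); at threshold τ a node earns
one point per group in which it reaches the top ⌈τ·n⌉ ranks in *any* member
parameter. Ties use competition ranking with boundary-inclusive inclusion —
deterministic and label-permutation invariant, at the cost of occasionally
including more than ⌈τ·n⌉ nodes. SV is monotone in τ by construction.

## Communities

k-clique percolation is run over the maximal cliques (Bron–Kerbosch with
pivoting): maximal cliques of size ≥ k are adjacent when sharing ≥ k−1
nodes, and a community is the union of a connected component of that
relation — provably identical to percolating individual k-cliques, and
verified against an exhaustive k-subset oracle on small graphs. Enumeration
aborts past a configurable maximal-clique bound (default 50,000) as a
safety valve. Note that two planted communities sharing ≥ k−1 densely
connected nodes merge into one percolation community by definition; the
cohesiveness clusterer below is the tool that separates such overlaps.

The cohesiveness clusterer greedily grows clusters from degree-ordered
seeds, maximizing f(S) = w_in/(w_in + w_bound + penalty·|S|) with
best-improvement add/remove moves (penalty 2.0 by default, mirroring common
protein-complex practice of penalizing boundary exposure of small sets),
discards clusters below `min_size`, and merges pairs with overlap score
|A∩B|²/(|A||B|) > 0.8. It is deterministic given the tie-break rules (label
order). It is a documented analogue of cohesiveness-based complex finders,
not a re-implementation of any specific tool, and no output equivalence is
claimed.

Community annotation is a one-sided hypergeometric over-representation test
per gene set (sets intersected with the analysis universe first), BH
adjusted across sets.

## Signature-reversal scoring

Reference = integer rank matrix, one column per perturbation instance, rank
1 = most up-regulated. For a tag set at sorted positions V(1..t) among N,
ES = a if a ≥ b else −b with a = max_j [j/t − V(j)/N] and
b = max_j [V(j)/N − (j−1)/t]. The definition is asymmetric by one rank
step: a top-packed set scores 1 − t/N, a bottom-packed set −(1 − (t−1)/N).
The combined score is (ES_up − ES_down)/2 when the two enrichments disagree
in sign and 0 otherwise; −1 is approached by perfect reversal as t/N → 0.

Per-drug significance: observed statistic = mean score over the drug's
instances; null = means of equally sized random instance subsets drawn from
the pooled scores; p = (1 + #{null ≤ obs})/(n_perm + 1), lower tail (the
reversal direction). Because the combined score has a point mass at exactly
0 (the same-sign rule), the null p-value distribution is uniform only below
the atom's quantile and conservative above it — calibration tests therefore
check lower-tail uniformity and global validity rather than strict
Kolmogorov–Smirnov uniformity. Candidates require p < α *and* negative mean
score. BH adjustment across drugs is available and is the pipeline default
(`perm_adjust: bh`); with multi-instance drugs it is what cleanly separates
planted reversers from the best-ranked null drugs. The raw permutation p
remains the library default.

## Synthetic data

All generators use numpy's PCG64; one seed fans out to per-stage substreams
via `SeedSequence.spawn`, so outputs are bit-identical across runs and
platforms.

* **Time course** — 4 time points (0, 2, 4, 24 h) × 2 replicates by
  default; baseline levels N(7, 1.5²) on log2 scale; per-gene variances
  scaled inverse-chi-square (d₀=4, s₀²=noise_sd², noise_sd 0.3 by default —
  a typical replicate-level log2 sd for summarized arrays); a 5 % planted
  fraction carries step profiles of amplitude 2 log2 units (alternating up/
  down) whose sign patterns always contain a ≥ 2-point same-direction run.
  Step profiles, not smooth curves: the analysis only uses consecutive-time
  contrasts.
* **GGM samples** — i.i.d. multivariate normal rows from chain / banded /
  random-sparse precision matrices (diagonally dominant by construction,
  positive definiteness verified).
* **Community graphs** — planted-partition: edge probability p_in inside a
  community, p_out elsewhere; communities may overlap.
* **Signature references** — reverser drugs rank query down-genes at the
  top and up-genes at the bottom, jittered by Gaussian rank-key noise;
  non-reversers are uniform permutations. Each drug can contribute several
  instance columns (default fixture: 50 drugs × 3 instances, 5 reversers —
  reversal is a minority phenomenon in real perturbation panels).

What the synthetic benchmarks do *not* show: the generators produce clean
Gaussian noise, balanced designs, and step-shaped effects; real microarray
data add probe effects, heavy-tailed outliers, correlated nulls and batch
structure. Passing the recovery tests demonstrates correctness of the
implemented statistics under their own model assumptions, not robustness to
violations of them.

## Problem sizes and runtime

The default test and acceptance runs use 400–5,000 genes, networks of tens
of nodes, 150-instance references and 2,000–20,000 permutations; these sizes
were chosen so the whole battery completes in well under a minute while
keeping every statistical check adequately powered. The pipeline itself has
no such limits — the `paper-like` fixture scale (10,000 genes, 600-column
reference, 100,000 permutations) runs in minutes.

## Known limitations

* The mixture-fdr fit uses a fixed central-quantile truncation (75 %); very
  dense true graphs (>25 % non-null pairs) would bias κ and make edge
  p-values anti-conservative.
* The cohesiveness clusterer is greedy; it has no optimality guarantee and
  its output depends on the documented tie-break order.
* The moderated F assumes a common d_g across genes (balanced design);
  unbalanced designs are rejected rather than approximated.
* Reproduction of the published VSMC analysis requires the original
  summarized expression files, which cannot be redistributed here; the
  reproduction test fails (by design) in their absence.
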