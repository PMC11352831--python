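# Methods

## Model and scope

`irrnet` analyzes deterministic synchronous Boolean dynamics on signed
regulatory networks. The unit of analysis is a *core* network: the largest
origon (subnetwork reachable from a root gene whose only incoming edges
are autoregulatory) after recursively removing nodes with no outgoing
edges to other nodes. Nodes outside the core cannot feed back upstream,
so their responses are determined by (and reversible with) the core; the
trimming is also the dimension reduction that keeps exhaustive 2^|V'|
state-space sweeps feasible. Out-degree for trimming excludes self-loops:
a node kept alive only by autoregulation still influences nobody else.

Assumptions inherited from the modeling framework: updates are synchronous
and deterministic; interactions are binary activation/repression (dual and
unknown edges are excluded at parsing, including regulator–target pairs
recorded with both signs); a gene's rule is a read-once monotone function
of its regulators; stochastic fluctuations, asynchronous update schemes,
and cell-cycle effects are out of scope.

## Rule ensemble

Every node with k incoming edges gets literals y_1..y_k (negated for
repression) ordered by regulator out-degree — ascending for *diffuse* and
descending for *concentrated* control, with lexicographic tie-breaks so
orderings are reproducible. The k−1 operators are drawn independently:
`×(` with probability r, `+` with (1−r)s, `×` with (1−r)(1−s). An open
parenthesis extends to the end of the expression (matching the trailing
")…)" closure of the sampling algorithm), and `×` binds tighter than `+`
inside each group. Rule realizations are unique at r = 1, at s = 0, and
at (r, s) = (0, 1), where M is forced to 1; elsewhere the default is
M = 20 realizations per (r, s) point and ordering.

Randomness uses one master seed with counter-based substreams derived from
(seed, realization, CRC32 of the gene name), so sampled rule sets are
independent of node iteration order.

**Autorepression.** A negated self-literal is evaluated as constant 0: by
ordinary negation when x_u = 1, and by a silencing assumption when
x_u = 0. One convention yields all the stated essentiality exceptions — a
self-literal in its own monomial vanishes from a sum, a conjoined
self-literal voids its whole monomial (partners become non-essential) —
and makes a pure autorepressor constant 0, hence monostable, excluding
artifactual period-2 oscillations. `check_consistency` reports these as
exemptions, not violations.

**Bias and canalization depth.** Rule bias is the fraction of input
vectors mapping to 1; at the unique-rule corners it equals 2^−k (all-AND)
and 1−2^−k (all-OR) exactly. Canalization depth of an input v is defined
as the size of the smallest partial assignment containing v that forces
the rule constant while the assignment without v does not (a minimal
certificate with v essential), computed by a dynamic program over all 3^k
partial assignments. This brute-force definition is used because the
original left-to-right buffer scheme is not fully specified in text; it
agrees with the fully canalizing corners (depth 1 for every input of a
pure AND or OR) and with the read-once examples (y1×(y2+y3 has depths
1, 2, 2). The depth function is exposed (`canalization_depths`) so an
alternative definition can be swapped in. Under this definition the
ensemble-average depth attains its grid maximum at (r, s) = (0.5, 1) for
k = 3..7, non-uniquely for k = 3, 4 where (0, 0.5) ties exactly.

Minimal sum-of-products forms come from a hand-implemented
Quine–McCluskey prime-implicant pass with essential-prime reduction and a
branch-and-bound minimum cover, tie-broken deterministically (cover size,
then literal count, then lexicographic implicant order).

## Dynamics and the perturbation protocol

States are integers over the sorted gene order (bit i = gene i).
Exhaustive attractor discovery builds the full vectorized successor table
(default cap 22 nodes) and labels every state by a memoized walk, so basin
sizes always sum to 2^n. Sampled mode probes random initial states
(without replacement when the state space allows) and is flagged
incomplete. The finder is pluggable so a constraint-solver backend could
be added for networks past the exhaustive cap; attractor counts at the
scale of the real 87-node core are only reachable that way and are not
reproduced here.

The transient protocol follows the five time points O→P→Q→R→S. The entry
state x^Q is the first recurrent state on the clamped trajectory, making
the protocol deterministic per phase. Release inverts the perturbed gene
back, x^R = g_u(x^Q) — deliberately *not* mere unclamping, since the
necessary/sufficient condition derivation fixes the inversion semantics.
For periodic attractors the perturbation is applied from every applicable
phase, and an attractor counts as irreversible for (u, type) if any phase
escapes; per-phase outcomes are retained so other conventions can be
recomputed. q_u counts an attractor as "on" if any of its states has
x_u = 1 (aligned with KO applicability). Undefined conditional
probabilities (no applicable attractor) are recorded as 0 with a flag,
consistent with the q-weighting of the aggregate. Basin weighting
replaces the uniform attractor weight inside the p^KO/p^OE fractions by
basin size and requires exhaustive mode.

Ensemble convergence uses the root-mean-square difference between
averaged profiles of two disjoint sub-ensembles of size M'; all
C(M,M')·C(M−M',M') ordered disjoint pairs are used when there are at most
1000, otherwise 1000 random pairs.

## Structural link and sign comparison

K_u sums the weights ω = Π 1/k^+ of all simple paths from u to any node
of 𝒦_u, the set of nodes in downstream SCCs (u's own included) carrying a
positive circuit, excluding u itself. Intermediate nodes are unrestricted
apart from simplicity — the alternative of excluding SCC-internal
intermediates is not stated anywhere authoritative, and the permissive
choice keeps K_u a pure path count. Positive circuits are detected by
exact simple-cycle enumeration with a configurable cap (default 10^6);
exceeding the cap is an error, never a silent approximation, because 𝒦_u
correctness depends on it. The power law p̂ = aK^b is fitted by least
squares in log-log space (the fitting procedure is not otherwise
specified; log-log least squares is the transparent choice), excluding
zero-valued genes rather than pseudo-counting so b stays interpretable;
R² is 1 − SS_res/SS_tot in log space with a degenerate-SS_tot → 0 flag.

TPM conversion is z_i = 10^6 (c_i/L_i)/Σ_j(c_j/L_j) with lengths in
kilobases. Observed signs are sgn(ln(ρ_u/⟨ρ⟩)) with ⟨ρ⟩ the mean fold
change over core genes (not over the whole transcriptome — the reference
shift should come from the genes being compared). Predicted signs follow
the polarity product along BFS shortest paths from the perturbed source,
negated for KO; equal-length paths of opposite polarity make the
prediction ambiguous, which counts as a match whenever the observed sign
is nonzero; unreachable genes are "not regulated" and excluded. Precision
ties in the magnitude ranking break lexicographically; the threshold on
|ln(ρ_u/⟨ρ⟩)| is strict (> 0.5).

**Bootstrap conventions.** Significance shuffles the predicted signs
while observed signs and magnitudes stay fixed; N_exc counts shuffles
whose statistic strictly exceeds the observed one out of N_samp = 25,000.
The standard exceedance p = N_exc/N_samp is reported as primary; the
complementary printed convention 1 − N_exc/N_samp is emitted alongside
because the two always sum to one and the complementary form is what some
reports print (it reads ≈1 exactly when the observed statistic is rarely
exceeded, which is inconsistent with small-p significance claims — the
intent is not guessed, both numbers are returned). For the
γ_irr − γ_rev statistic a shuffle counts toward N_exc only if it exceeds
the observed difference in *both* cultivation conditions.

## Synthetic data

The network generator draws directed edges independently (default
repression fraction 0.3, matching the roughly one-third repressive share
typical of bacterial regulatory annotations) and injects a requested
number of disjoint mutual-activation two-cycles, the minimal positive
circuits, so circuit content is controllable; `random_core_network`
additionally enforces minimum in-degree 1 and weak connectivity to mimic
a trimmed origon core. The expression generator draws lognormal baseline
means, multiplies evolved means by exp(σ_u^true · effect) with σ^true
taken from the shortest-path polarities (ambiguous genes get a recorded
random ±1 so the ambiguity branch is exercised), adds per-gene
multiplicative lognormal noise and per-replicate lognormal library-size
factors (σ = 0.1) so TPM normalization is non-trivial, and scales counts
by gene length. Defaults (effect 1.0 on the log scale, 3 replicates,
lengths 0.3–3 kb) give above-threshold magnitude sets comparable to the
tens of genes seen in real evolved-vs-wild-type comparisons.

What the generator does *not* emulate: realistic degree distributions or
operon structure, count overdispersion beyond lognormal noise, batch
effects, or any coupling between expression level and regulatory role.
Passing tests therefore demonstrate correctness of the pipeline's
computations and conventions on data satisfying its assumptions — not
that real expression data will show the same concordance.

## Problem sizes and numerical choices

Test and acceptance sweeps use networks of 3–12 nodes with exhaustive
attractor search (state spaces ≤ 2^12), ensembles of M ≤ 20, and
bootstrap sizes of 499–25,000; these sizes make every sweep exact
(complete state spaces, complete rule enumerations for the theorem
checks) while keeping the whole suite to a few minutes. Probability
comparisons use exact arithmetic where the quantities are ratios of small
integers (fixture values like p^OE = 2/3 are asserted exactly);
floating-point tolerances elsewhere are 1e-12. Attractors are
canonicalized to start at their smallest state, making set comparisons
phase-invariant.

## Known limitations

- A cross-check worth stating plainly: positive circuits are necessary
  for multiple *fixed points* (verified exhaustively here), but
  irreversibility itself can occur without them — coexisting periodic
  attractors of intertwined negative cycles can be phase-shifted by a
  transient clamp. On random small networks this happens routinely, so
  "no positive circuit ⇒ reversible" must not be read as a theorem; it
  holds for fixed-point-dominated dynamics like the empirical core
  network's. Likewise positive circuits do not *guarantee* a multistable
  realization (negative feedback can interlock them); multistability is
  guaranteed only in aggregate over the generated positive-circuit
  ensembles.
- Exhaustive attractor search is capped at 22 nodes; beyond that only
  sampled (incomplete) discovery is available in-package.
- The canalization-depth definition is a faithful but independent
  reconstruction; alternative buffer-based definitions may differ on
  non-read-once functions.
- Path enumeration for K_u is exponential in the worst case; the cap
  errors out rather than approximating.
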