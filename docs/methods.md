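# Methods

## The modeling problem

Public bioactivity databases report, for each compound, outcomes of many
heterogeneous assays: different standard measures (K_i, IC50, efficacy
percentages, ...), assay protocols, organisms and molecular or cellular
targets. The package models the binary link L_ij(c_q) — does drug d_i give
a strong outcome against target t_j under the assay conditions c_q — as a
function of a single topological descriptor of the compound plus
moving-average terms that situate the compound relative to the active
chemistry of each condition.

## Markov–Shannon entropy descriptors

A molecule is a hydrogen-suppressed graph whose atoms carry Pauling
electronegativities χ. A Markov chain walks the graph: from atom i the
walker moves to j ∈ N(i) ∪ {i} with probability χ_j normalized over that
destination set. With the start distribution p₀(j) = χ_j / Σχ, the order-k
descriptor is the Shannon entropy of the k-step state distribution,

    θ_k = −Σ_j p_k(j) log₂ p_k(j),    p_k = p₀ Πᵏ.

θ_k is invariant to atom relabeling, bounded by log₂ n with equality on
vertex-transitive graphs with uniform χ, and positive for connected graphs
once k reaches the diameter. The activity model uses θ₅ only; orders 0–4
are computed and exported for diagnostics.

Numerical conventions, each of which changes the descriptor values and is
therefore pinned:

* **Self-loops** are included in the destination set (configurable). They
  keep the chain defined on single atoms and isolated fragments.
* **Base-2 logarithms** (bits), configurable via the encoder's `base`.
* **Electronegativities** come from the embedded Pauling table in
  `electronegativity.py`; charged atoms use the neutral element's value.
* **Disconnected inputs** (salts): the largest connected component is kept
  by default — a Markov chain never mixes across components — with a flag
  to keep everything.

Published θ values for specific compounds are not reproduced bit-exactly:
the original descriptor software's normalization conventions are not
restated in the literature, so agreement is structural (the invariants
above), not numeric.

## Moving-average features and the discriminant

For each condition class (measure s_x, assay a_u, organism o_t, target
t_j) and value c, the active-set moving average is ma(c) = p₁(c)·⟨θ₅(c)⟩,
where p₁(c) = n₁/n is the fraction of active records under c and ⟨θ₅(c)⟩
averages the descriptor over active records only. A record's feature
vector is

    [ p(c_l)·θ₅,  θ₅−ma(s_x),  θ₅−ma(a_u),  θ₅−ma(o_t),  θ₅−ma(t_j) ],

with p(c_l) ∈ {1.0, 0.75, 0.5} the data-quality weight of the curation
level. The score is affine, S = a₀ + a·f, fit by two-class linear
discriminant analysis with pooled within-class covariance and empirical
priors; the intercept places the decision boundary at posterior 0.5 and
the logistic map of the score is then the exact class posterior. Labels
are predicted 1 when the probability strictly exceeds the cutoff (default
0.5); a probability exactly at the cutoff is classed 0.

The package ships `data/reference_model.json`, the published coefficient
set. For that fixed model no probability link was published; the logistic
link is used and documented as an approximation — only the score itself is
exact. MA statistics are always computed on training records and frozen;
prediction rows never contribute labels. Unseen condition values at
prediction time raise in strict mode (default) or fall back to the global
active-set average in lenient mode.

Fit diagnostics: R_c is the Pearson correlation between the discriminant
score and the labels (the two-class canonical correlation), and χ² is
Bartlett's statistic −(N−1−(p+2)/2)·ln(1−R_c²). They describe the fit at
hand; the published values depend on the original data extract and are not
reproduction targets. A singular pooled covariance aborts the fit with
advice to set the `shrinkage` parameter rather than silently regularizing.

## Evaluation conventions

Confusion matrices are reported as row-wise correct rates keyed by the
observed class plus overall accuracy, at full precision internally and one
decimal in reports. The published table layout pairs the label "Sp" with
the observed-link row and "Sn" with the observed-0 row — the reverse of
the conventional orientation; the report reproduces that layout by default
and offers the conventional mapping behind a flag. Only the labels move;
counts and rates are identical.

## Tripartite networks

Every positive outcome (observed label, or predicted probability strictly
above the cutoff) contributes the arcs d→t, d→a and t→a; duplicates
collapse; measures and organisms are deliberately not nodes (they would be
near-universal hubs). Node ids are namespaced (`d:`, `t:`, `a:`) so a
string reused across classes cannot collide. A `path_only` flag omits the
d→a shortcut. Per-node statistics are computed on the symmetrized graph
with self-loops and uniform weights: Π(i,j) = 1/(deg(i)+1) on
N(i) ∪ {i}, π₁ = u·Π from the uniform start, and the first-order
Markov–Shannon node entropy is Sh₁(i) = −π₁(i)·log₂ π₁(i), in bits. On an
n-node vertex-transitive graph every Sh₁ equals (1/n)·log₂ n, which at
n ≈ 2500 gives the 10⁻³-scale values typical of the published network
tables; exact reproduction of those tables would require the original
extract.

## Synthetic data generator

The generator emulates the statistical structure of a large curated
extract — by default 3548 records over 3091 compounds, 37 measures, 493
assays, 11 organisms and 169 targets — with a planted model so that every
downstream component is testable without downloads. Three design choices
matter, and each addresses a specific failure mode:

* **Chemically stratified conditions.** Every condition value carries a
  descriptor center, drawn by mapping its configured activity prior
  (uniform on [0.2, 0.95] by default) increasingly onto the descriptor
  range, and records sample compounds near their conditions' centers
  through a Gaussian preference kernel of width 0.6 bits. Real assays
  probe particular chemical series; statistically, this cross-condition
  heterogeneity is what makes the four deviation features linearly
  independent. Without it all condition averages coincide and the planted
  direction is unidentifiable.
* **Expected-label fixed point.** The MA statistics depend on the labels
  and the labels on the statistics. Label probabilities are solved as a
  damped fixed point (damping 0.5, tolerance 1e-7, at most 80 iterations)
  of the map probs → soft statistics → scores → probs, where the soft
  statistics replace hard counts by their expectations (p₁ = mean
  probability, probability-weighted θ mean). The final labels are a single
  Bernoulli draw from the converged probabilities. Statistics recomputed
  from the drawn labels then converge to the generating statistics as
  condition subsets grow — the property that makes refitting the
  discriminant a consistent estimator of the planted direction. A naive
  alternate-and-redraw scheme oscillates (the stats↔labels map has loop
  gain below −1) and leaves refit-time features far from the generating
  ones.
* **Link calibration.** Labels follow Bernoulli(σ(scale·(S − midpoint)))
  with scale 6.0 and midpoint 1.3. The scale gives label determinism
  comparable to a strongly separating discriminant (refit R_c ≈ 0.6); the
  midpoint centers the label law inside the planted score distribution so
  the overall activity rate lands near 40% — between a balanced design and
  the minority-active balance of the modeled extract — instead of the
  saturated >80% a zero midpoint produces. A `step` link yields noise-free
  labels exactly separable by the planted score.

The planted coefficients default to the shipped reference set. Configured
condition priors steer the empirical per-condition activity rates through
the chemistry map and correlate strongly with them at realistic subset
sizes, but are not reproduced exactly: the labels are fully determined by
the five features, which is what keeps the refit well-specified. Molecules
are assembled from drug-like ring and chain fragments over C/N/O/S;
generation is byte-deterministic under the seed, and degenerate one-class
draws are retried on fresh substreams with a warning.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline recovers a planted linear structure of exactly the form
the model assumes, at the dataset shapes it targets. They do not show that
real bioactivity data has that structure, that real condition subsets are
single-peaked in descriptor space, or that a single topological descriptor
suffices for real chemistry.

## Problem sizes used in the checks

Parameter recovery is exercised at 5000 records over 1500 compounds with
12/40/5/25 condition values per class (cosine to the planted direction
≥ 0.9; smaller runs at 500 and 2000 records check that the cosine grows
with n). The end-to-end train/holdout check runs the full default dataset
shape with a stratified 75/25 split, lenient condition lookup on the
holdout, and requires balanced accuracy of at least 60% (chance is 50%
regardless of class balance). These sizes are the package's own test
design.

## Known limitations

* The descriptor normalization matches the conventions stated above, not
  necessarily those of the original descriptor software; absolute θ values
  may differ from published ones by convention.
* The fixed reference model's probabilities are logistic-approximate; only
  scores are exact.
* The generator's chemistry is combinatorial fragment assembly, not a
  sample of real chemical space; its condition structure is single-peaked
  by construction.
* Multi-label outcomes, regression endpoints and descriptor-order
  selection are out of scope; the model uses θ₅ only.
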