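# Methods

## The generative model

A two-channel RT-stop experiment is modelled per molecule. Reverse
transcriptase (RT) primes in the 3' linker and copies positions
`L, L−1, …, 1` in order. At every position `k` it reaches, it may
terminate spontaneously with natural hazard `γ_k ∈ [0, 1)` (failing to
add nucleotide `k`, so the last synthesized base is `k+1`). In the
reagent-treated (+) channel a molecule additionally carries, with
probability `p_mod`, a single adduct at site `s` drawn from the
distribution `θ` (single-hit regime); RT stops with certainty upon
reaching `s`. Stop index 0 denotes full-length read-through. The exact
stop distributions are

```
P−(k) = γ_k · Π_{j>k}(1−γ_j),             P−(0) = Π_j(1−γ_j)
P+(k) = Π_{j>k}(1−γ_j) · [ γ_k(1 − p_mod·T_k) + p_mod·θ_k ],   T_k = Σ_{s≥k} θ_s
P+(0) = (1−p_mod) · Π_j(1−γ_j)
```

Assumptions worth stating: at most one adduct per molecule (the low-
modification titration point the θ formalism presumes); RT blockage at an
adduct is certain; natural drop-off is independent of modification
status; no PCR duplication or ligation bias (the simulator does not
emulate them either).

## The estimator and why it has a survival product

The minus-channel likelihood factorizes over per-position stop hazards,
so the natural-hazard MLE is the empirical hazard `β_k = Y_k/Σ_{j≤k}Y_j`;
`γ` is profiled from the (−) channel alone, since that channel carries no
information about `θ` and serves exactly this control role. Substituting
`γ̂ = β`, the plus-channel likelihood also factorizes over hazards, with
per-position stop hazard `a_k = γ_k + (1−γ_k)·m_k` where
`m_k = P(modified at k | RT reached k)`. The unconstrained hazard MLE is
the empirical `α_k`, giving

```
m_k = max(0, (α_k − β_k)/(1 − β_k))
```

(the clamp is the boundary solution when sampling noise pushes the (+)
hazard below background; because the likelihood is separable across
positions, clamping one position does not perturb the others). The map
from conditional hazards to the unconditional site distribution inverts
as `u_k = m_k · Π_{j>k}(1 − m_j)` — a molecule is modified at `k` only if
no more-3' site already stopped it — whence `p̂_mod = Σ u_k` and
`θ̂ = u / Σu`. This is the exact maximizer of the stated likelihood; we
verified it against numeric maximization over the simplex (the test
suite's independent oracle) to 1e−3 per coordinate. The familiar ratio
form `θ̂ ∝ m` drops the survival product; it is the small-hazard
approximation (`m_k ≪ 1`), kept in the results as `theta_ratio` for
comparison but not used.

Uncertainties: `theta_se` is a first-order delta-method propagation of
the binomial hazard variances through the closed form, neglecting
cross-position covariance; treat it as a diagnostic scale, not an exact
interval.

Degenerate inputs: if every `m_k` clamps to zero (no modification signal)
the profile is returned all-zero with a `degenerate` flag rather than
raising; positions never reached in a channel, or with a saturated (−)
hazard (`β_k = 1`), are flagged and contribute zero rather than being
imputed. The sum-to-one identity (tolerance 1e−9) is asserted on every
non-degenerate fit.

## Coordinates and the 3'-terminal exclusion

Positions are 1-based; a fragment whose 5'-most aligned position is `p`
is attributed stop index `k = p − 1` (the blocking site is one nucleotide
5' of RT's last synthesized base). This offset convention is what makes
the simulator's planted reactive sites recover at their own positions; if
changed, every spectrum shifts by one. The position adjacent to the
linker (`k = L`) is excluded from estimation by default — a
single-nucleotide fragment cannot be uniquely assigned — so the scored
length is `L' = L − 1` and `ρ = L'·θ` has mean 1 over the scored range.
The exclusion is configurable off.

## Read processing

Channel handles are IUPAC-degenerate prefixes of R1 (defaults RRRY for
(+), YYYR for (−)); a read matching both or neither is counted
unassigned. Adapter read-through is removed by longest-suffix/prefix
matching with a minimum overlap (default 4) and a mismatch-rate cap
(default 0). Alignment is exact substring matching (Hamming tolerance
configurable, default 0 mismatches) of R1 against target+linker, with R2
checked for consistency from the linker side; reads matching more than
one (target, position) are discarded as ambiguous rather than randomly
assigned, which would bias hazard estimates at repeats. Because an
adapter overlap shorter than the trimmer's minimum is untrimmable by
construction, the aligner soft-clips up to `min_overlap − 1` trailing
bases that extend past the end of target+linker; without this, every
stop within a few nucleotides of the linker is lost. Base qualities are
carried but not filtered on by default; an optional minimum-mean-quality
filter is provided.

## The simulator: what it emulates and what it does not

`simulate_stop_counts` samples per-molecule stop indices from the exact
stop distributions above (equivalent to the positional walk);
`emit_fastq` lays each molecule out as sequenced: instantiated degenerate
handle + cDNA fragment (target sense) + linker on R1, reverse complement
from the linker side on R2, adapter read-through when the insert is
shorter than the read length (default 35 nt), optional uniform
substitution errors, uniform qualities. Identical parameters give
byte-identical FASTQ.

Default study conditions, chosen once as a realistic operating point:
modified fraction `p_mod = 0.25` (a Poisson modification intensity of
λ ≈ 0.3 gives P(≥1 adduct) ≈ 0.26 with ~95% of modified molecules
carrying exactly one hit — the textbook single-hit titration point);
natural hazards `γ_k` uniform in [0, 0.05], matching the few-percent
per-position drop-off of routine RT reactions; structured θ with ~20% of
positions strongly reactive (loop-like) over a low baseline, zero mass at
the linker-adjacent position; 100,000 molecules per channel for recovery
and replicate studies, 50,000 per channel for read-level studies (sizes
at which the identities and recovery targets below are comfortably
resolved while the full suite runs in well under a minute).

Not emulated: PCR duplicates and amplification bias, ligation sequence
preference, indel sequencing errors (the aligner is substitution-only by
design), quality-score realism, multi-hit modification. Passing tests
therefore demonstrate correctness of the computational pipeline under
the stated stochastic model, not robustness to those experimental
artifacts.

Measured under the default conditions (seeded, reproduced by the test
suite): θ recovery at L = 50 with mean absolute error ≤ 0.005 per
position and Pearson r ≥ 0.99 against truth; independent replicate
simulations correlate at r ≥ 0.99; read-level processing reproduces the
simulator's internal stop tallies exactly at zero sequencing error. The
per-position maximum error at these sample sizes is of order 0.01 at
strongly reactive sites (binomial noise: sd(θ̂) ≈ 0.003 there), which is
why recovery is characterized by MAE and correlation rather than a
uniform bound.

## Scoring and constraints

Sensitivity = correctly predicted / accepted pairs; PPV = correct /
predicted pairs; integer numerators and denominators are always
reported. With slippage on (default, mirroring common scorer behaviour)
a predicted pair (i, j) may be credited by an accepted (i±1, j), (i, j±1)
or (i, j); each accepted pair is creditable at most once, enforced by
maximum bipartite matching so the credit count is order-independent.
Empty accepted (or predicted) sets make sensitivity (or PPV) undefined,
reported as not-applicable. Both slippage modes are first-class; an
exclusion mask removes positions (e.g. 5' synthesis scaffolding) from
scoring. Constraint files are two-column (1-based index, ρ) with −999 as
the no-data sentinel, the format SHAPE-aware folding engines consume;
the thermodynamic folding itself is out of scope — this package emits
constraints and scores foldings, it does not fold.

## Design choices where the design was open

- **Model/Results shape.** The estimator is exposed as a fitted-model
  pair (`ReactivityModel.fit() → ReactivityResults` with `summary()`),
  with functional wrappers for pipeline use.
- **Estimator form.** Exact-MLE survival-product form rather than the
  ratio approximation (derivation above); the approximation is preserved
  as a diagnostic.
- **Clamping before normalization.** Negative raw signals are clamped to
  zero before normalizing, so θ is never negative; unclamped values stay
  in `raw_signal`.
- **p_mod as nuisance.** θ is the conditional site distribution; the
  absolute modification rate is estimated and reported but not part of
  the reactivity output.
- **Distribution comparisons** align on shared scored positions, drop
  no-data pairwise, and by default exclude the full-length (k = 0) bin
  (reactivity-bearing positions only; configurable by slicing).
- **Pseudoknots** are rejected by the dot-bracket parser, not silently
  dropped — silent loss would corrupt PPV.

## Known limitations

Single-target alignment is exhaustive substring search — fine for target
panels of short RNAs (the intended regime), not for transcriptomes. The
delta-method standard errors ignore covariance induced by normalization.
The likelihood evaluation reports −inf (distinctly) when counts occur at
model-probability-zero positions; fitted models on sparse data can
legitimately produce this for their own diagnostics' `llf`.
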