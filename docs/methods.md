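# Methods

## Model and rationale

Horizontal transposon transfer (HTT) is inferred from three mutually
reinforcing signals, none of which is individually decisive:

* **Phylogenetic incongruence.** Under vertical inheritance, TE copies
  should mirror the organismal phylogeny at every taxonomic rank. A
  label-uniform clade of copies nested inside another order's (or
  superfamily's) clade contradicts that expectation.
* **Divergence-time deviation.** Neutrally evolving TE copies separated at
  time *T* accumulate *K* ≈ 2 *r T* differences per site, so
  *T* = *K* / (2 *r*). When the dated species split is an order of
  magnitude (θ ≥ 10) older than the TE-based *T*, vertical descent would
  require implausible rate suppression.
* **Geographic overlap.** Transfer requires contact; copies exchanged
  between species sampled in (or distributed across) the same coarse
  biogeographic region are more plausible transfer partners. Geography
  only corroborates — it never creates a call on its own.

Direction of transfer is not inferred: topology and distances constrain
the event, not its polarity. Donor/recipient identities exist only in the
simulator's truth logs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` (= μ) | 3.0 × 10⁻⁹ /site/generation | neutral substitution rate for insects; under neutrality the substitution rate equals the mutation rate |
| `generations_per_year` | 1 | conservative floor (most insect taxa have ≥ 2 generations/year), biasing *T* upward |
| identity floor | > 80% | per-HSP nucleotide identity for retention |
| coverage floor | > 70% | stitched HSP union over the query (3,705 bp of 5,294 bp); comparisons strict, matching the "> 80% / > 70%" convention |
| support threshold | 0.7 | SH-aLRT-style branch support below which edges are contracted to polytomies |
| θ | 10 | minimum species-time / TE-time ratio for deviation evidence; one order of magnitude, well below the two-to-three orders seen in clear transfer cases |
| evidence weights | 1 / 1 / 0.5 | incongruence / deviation / geography contributions to the candidate score |

*K* is the **uncorrected** p-distance under pairwise deletion (gaps, N and
IUPAC ambiguity codes treated as missing) — the "base differences per
site" statistic of MEGA — because the clock arithmetic that produces the
headline estimates (0.0751 → ~12.5 MY; 0.00983 → ~1.64 MY; identity 0.80 →
~33 MY) uses *K* uncorrected. A Jukes–Cantor correction
(−¾ ln(1 − 4p/3)) is available as an explicit opt-in but is nowhere the
default. Note the open question this leaves: a "0.068 MY" class of
estimates derived from identities quoted only as "> 99.95%" is not
reproducible because the underlying *K* is unrecoverable; such values are
not asserted anywhere.

## Identity rule with multiple HSPs

Whether identity should be assessed per HSP or length-weighted across a
subject's HSPs is under-determined by the "> 80% identity" convention.
The per-HSP reading is used: HSPs at or below the floor are discarded
before coverage stitching, which is the conservative choice (a subject
cannot ride a low-quality HSP into the coverage union). Interval
arithmetic converts the 1-based inclusive tabular coordinates to 0-based
half-open internally; minus-strand subject ranges are normalized to
(min, max), while query coordinates are ascending by construction.
Disjoint same-subject clusters separated by more than one query length
become separate TE copies (multiple insertions per scaffold).

## Parsimony, canonical labeling, tie-breaking

Minimum label changes are computed by Sankoff dynamic programming with
unit costs over arbitrary out-degree (support collapsing creates
polytomies, so Fitch's binary recurrence is insufficient), plus an
up-pass giving, per node, the set of states attainable in *some*
minimum-cost labeling. `excess_events` = score − (n_labels − 1) is the
transfer lower bound; it is 0 exactly when every class is monophyletic.

Edge attribution needs one concrete optimal labeling. The canonical
resolution assigns the root its cheapest state and resolves ties downward
by preferring a state change near the root (accelerated-transformation
style), then lexicographically; children are ordered by smallest
descendant leaf id, so the labeling is reproducible. An edge whose
above-edge optimal state set has more than one member is flagged
`ambiguous`; headline counts should use unambiguous records only.

Per focal label, the transition edge subtending the largest label-uniform
clade is designated that class's origin (`basal_origin`) rather than an
incongruence; a label equal to the root's background state gets no such
designation. Consequences worth knowing:

* a fully congruent tree yields n_labels − 1 transition edges, all basal,
  and zero incongruences;
* a class that is monophyletic but *nested* (e.g. a single sampled copy of
  one order sitting inside another order's clade) is not counted as an
  incongruence — the deviation-ratio channel catches such cases instead;
* when one donor seeds several recipients, the donor's own copy sits
  inside the recipient cluster and parsimony may attribute the transition
  to the donor's edge — topology alone cannot say which side moved. This
  is the main source of (near-boundary) false positives in the end-to-end
  experiment.

The parsimony score is root-invariant; edge attribution is not, so the
tree is rooted deterministically first — at the midpoint when branch
lengths exist, else at the MRCA of the largest label class (configurable).

Note that the score is monotone under label refinement (splitting classes
can only add changes) but `excess_events` is not, since n_labels − 1 grows
too; per-rank tables therefore floor the "additional events at the finer
rank" at zero rather than assuming monotonicity.

## Support handling and collapsing

Supports are read from internal-node Newick labels, in [0,1] or [0,100]
(auto-detected by the maximum, overridable). Contracting an edge promotes
its children with their own branch lengths and drops the contracted
length — the standard polytomy contraction (as in `ape::di2multi`);
paths through the contracted edge shorten accordingly. Collapsing is
idempotent and never changes the leaf set.

## Simulator

The simulator realizes exactly the model the clock arithmetic assumes:
one TE copy per lineage evolving by Jukes–Cantor at rate μ along a dated
(ultrametric, branch lengths in years) species tree. A transfer at time
*t* is implemented as a regraft: the recipient's branch is detached at
*t* and reattached to the donor's branch, so the recipient's copy *is*
the donor's copy at the event time and both evolve independently
afterwards. Substitutions are drawn per site as Poisson(μ·generations)
events, each replacing the base with one of the other three uniformly
(the post-event base distribution is computed in closed form, so the
realization is exact and fast); per-branch event counts go to the truth
log. Event times must fall within the named lineage's parent-edge span,
and a donor inside the detached recipient clade is rejected (it would
create a cycle).

What the simulator deliberately does **not** model: indels (the emitted
"alignment" is the trivial gap-free one), selection, rate variation among
sites or lineages, within-genome copy-number dynamics (bursts,
excision), and assembly/sequencing artifacts. Passing end-to-end tests
therefore shows the inference chain is sound under its own model
assumptions — not that real screens are free of alignment error,
contamination, or rate heterogeneity, which real analyses must handle
upstream. Degradation is modeled only as truncation (a uniform fraction
of the element's length), which is what the coverage filter actually
sees.

The canonical stress scenario (`recent_ht_scenario`) uses 5 orders × 4
species splitting 300 MY ago (within-order splits up to 120 MY), a
5,294 bp element, μ = 3 × 10⁻⁹, one generation per year, and 5 transfers
between orders injected at 0.2–1.0 MY — recent transfers between
anciently diverged lineages, the regime the evidence chain targets. At
these depths the uncorrected p-distance saturates (~0.68 between orders),
which compresses deep branches in the closed-loop NJ tree but leaves
order clades and the nested recipient copies intact.

## Numerical and degenerate-input choices

* Distances: pairs with zero comparable sites raise an explicit
  undefined-distance error scalar-wise and become NaN cells matrix-wise;
  downstream means skip NaNs.
* `T` with *K* = 0 is exactly 0; a dated split against *T* = 0 gives an
  infinite deviation ratio, which is treated as exceeding any finite θ.
  θ = ∞ disables the deviation channel entirely.
* Neighbor joining validates symmetry, zero diagonal and n ≥ 3; on
  additive matrices path lengths are reproduced to 1e-9.
* All simulator randomness flows through a single seeded NumPy generator
  in a fixed traversal order; equal seeds give byte-identical output
  files, and candidate calling contains no randomness at all.

## Problem sizes

The test-suite and acceptance-script experiment sizes — 500 random trees
(≤ 12 leaves, ≤ 4 labels) for the exhaustive-parsimony comparison, 1,000
random HSP sets for the coverage bitmap, 200 additive matrices for NJ
recovery, and 20 replicate simulations at 5 kb for calibration and
end-to-end recovery — were chosen as the smallest sizes at which the
stochastic checks are statistically meaningful (3-SE bands, ≥ 100 total
injected events) while keeping every run a desk-scale computation.
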