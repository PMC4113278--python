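# Methods

## Accurate-mass annotation

Neutral monoisotopic masses are sums of per-element monoisotopic
constants (C = 12 exactly, H = 1.00782503207, N = 14.0030740048,
O = 15.99491461956, Na = 22.9897692809, with S and P available), all
pinned in `netpharm.constants` so the arithmetic can be audited in one
place.  Adduct m/z values add a fixed offset to the neutral mass that
accounts for both the charge carrier and the electron:
[M+H]⁺ = +1.00727647, [M−H]⁻ = −1.00727647, [M+Na]⁺ = +22.98922070,
[M+CH₃COO]⁻ = +59.01385292 Th.  Mass error is
(measured − expected)/expected × 10⁶ ppm and the retention window
defaults to 5.0 ppm.  Internal arithmetic is full double precision;
display rounds to 5 decimals, half-even.

Annotation ranks retained candidates by (previously-reported flag,
|ppm|, compound id).  The prior flag encodes the convention that, among
isobaric candidates, a compound already reported in the preparation is
the likelier identity; the remaining tie-breaks are deterministic so
the ranking is a total order and permutation-invariant.  Two genuine
degeneracies deserve note.  First, [M−H]⁻ of a formula and [M+CH₃COO]⁻
of the formula minus C₂H₄O₂ are the *same ion* and hence exactly
isobaric; no mass-based rule can separate them, and the test suite
accepts either.  Second, several identified rows of the reference
table correspond to ammonium adducts ([M+NH₄]⁺, +18.03383), which are
outside the four-adduct model; they are ingested verbatim but excluded
from round-trip annotation checks, as are "unknown" rows whose printed
formulas are anion compositions.  Isotope-pattern vetting is a
pluggable hook (`isotope_filter`) that accepts everything by default —
no scoring rule is defined for it here.

## ADME filters

The absorption filter keeps compounds with Papp strictly above the
cutoff, in units of 10⁻⁶ cm/s.  The default is 7.0 (the Yazdanian
"excellent oral absorption" criterion); 9.0 is the common stricter
alternative and both are exercised by the tests — on the packaged
table they retain 22 and 20 constituents respectively.  Records with
no Papp prediction (unidentified peaks) are dropped.  The metabolite
filter keeps a predicted reaction site when score ≥ 0.6 **and**
reliability ≥ 0.5, and a metabolite when at least one of its sites
survives.  The comparisons are deliberately inclusive: the reference
predictions retain a metabolite at reliability exactly 0.5, so a
strict reading would contradict the data the thresholds describe.
Both filters are idempotent and monotone in their thresholds, and
these invariants are property-tested.

## Similarity screening

Similarity is Tanimoto over caller-supplied binary fingerprints, with
|A∪B| = 0 defined as similarity 1 (two empty fingerprints are
indistinguishable).  A library drug is a hit when similarity is
strictly greater than 0.85; the boundary value is excluded.  Targets
of hit drugs are pooled as a set union, with the per-compound
breakdown preserved for the bipartite network; hit drugs missing from
the target map are skipped, warned about, and counted.

## Networks and topology

The merged PPI graph is simple and undirected: self-loops are dropped,
duplicate edges collapse with a union of database tags, and accessions
can be normalized through a user-supplied two-column map (unmapped ids
pass through verbatim and are reported).  The target sub-network is
the induced subgraph on putative ∪ known targets plus neighbors within
radius 1 (configurable); isolated seed targets are retained so node
counts stay auditable.

Betweenness is reported raw (sum of σ_st(i)/σ_st over unordered pairs,
endpoints excluded) and normalized by (N−1)(N−2)/2.  Closeness is
reported in two scales: the literal inverse summed distance 1/Σd
within the node's component, and the conventional (n_comp−1)/Σd.  The
literal scale is the screening default; both are always computed
because the two scales differ by a size factor that matters whenever
absolute cutoffs are transplanted between networks.  The k value is
the core number from iterative deletion of vertices of degree < k.
Computation is delegated to networkx; correctness is established in
the test suite by exhaustive brute-force oracles (all-simple-path
enumeration, Floyd–Warshall, direct deletion simulation) on hundreds
of small random graphs.

A node is a **hub** when its degree strictly exceeds 2 × the median
degree (midpoint convention for even counts).  **Major hubs** are
screened on the subgraph induced by the hubs — not the parent network —
by recomputing all four measures there and requiring each to strictly
exceed its median over hub nodes; explicit cutoffs can be injected in
place of the medians when replicating a published screen.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) with Benjamini–Hochberg adjustment across tested sets — the
field-standard choice, made explicitly here because the procedure is
otherwise underdetermined.  The background defaults to the union of
all gene-set members unless supplied.  Only sets overlapping the query
are reported, ranked by p then id.

## Synthetic data

The generator replaces inputs that cannot ship with the package and is
itself first-class, tested code.  Defaults are fixed at study scale:
48 compounds with log-normal Papp whose median sits at the 7.0 cutoff
(so the exceedance probability at the cutoff is exactly 0.5 and
retention can be checked against it); a preferential-attachment
interactome of 2397 proteins with 2 edges per arriving node, matching
the scale and heavy-tailed degree structure the hub analysis presumes;
planted hubs wired host-by-host until each strictly exceeds
2 × the realized median degree with a 50 % relative margin, so hub
recall must be 1; a 200-drug library of 95-bit/1024-length
fingerprints in which each query compound has exactly one planted
near-duplicate at Jaccard exactly 0.9 (90 shared bits of 100 united —
realizability of the requested similarity is checked by exact rational
arithmetic and unrealizable requests are configuration errors), while
baseline drugs sit near Jaccard 0.05; and 50 pathways of 40 members
over a 2000-protein universe with a query of 25 drawn 80 % from one
planted pathway.  All randomness derives from a single seed through a
fixed `SeedSequence` spawn order, so outputs are byte-identical across
reruns.

What the synthetic data does *not* emulate: real chemistry (no
structures, no fingerprint–structure relationship), interactome
features beyond degree heavy-tails (no clustering, no complexes, no
database-specific biases), and correlated ADME predictions.  Passing
tests therefore demonstrate that the algorithms implement their
definitions and recover planted structure under the stated generative
assumptions — not that the biological conclusions of any particular
screen are correct.

## Problem sizes and numerical choices

Property checks run at sizes where their error bounds are meaningful:
oracle agreement on 200 random graphs of ≤ 8 nodes (exhaustive
enumeration is exact there), hub recall over 20 seeds at 500 proteins,
null calibration of the enrichment p-value over 2000 simulated
queries (asserting the rejection rate at 0.05 stays ≤ 0.07 — the
discreteness of the hypergeometric makes the test conservative, and
observed rates are near 0.01), and Papp retention at 10,000 draws
(binomial 3σ ≈ 0.015).  Floating-point comparisons against oracles use
absolute tolerances of 1e-9 (betweenness, accumulated fractions) and
1e-12 (closeness); published m/z cells are matched at their printed
5-decimal precision.

## Known limitations

The full published network results (a 2397-node merged interactome,
463 hubs, the literal major-hub cutoffs 3 / 0.06 / 31.30 / 3, 106
major hubs) depend on eight 2012-era database snapshots and an
unpublished commercial similarity algorithm and cannot be regenerated
from first principles; the package reproduces the *rules* and exposes
the published cutoffs as injectable overrides instead.  Which
betweenness normalization and closeness scale produced the published
medians is undeterminable from their values alone, which is why both
variants of each are first-class outputs.  The similarity stage is
explicitly a Tanimoto stand-in for an unpublished score family, with
the threshold semantics (> 0.85, strict) preserved.
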