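# Methods

## Model

A *variation graph* is a directed acyclic graph whose vertices carry
nucleotide labels, together with a nonempty set of distinguished
source-to-sink paths P, each representing a known haplotype (in the
motivating setting, the alleles of a bacterial gene across strains).  An
unlabelled virtual source and sink bracket every path.  All alignment runs
on the *canonical* form of the graph, in which every labelled vertex
carries exactly one character; multi-character segments are expanded into
chains and an origin map remembers, for each canonical vertex, its source
segment and offset (used for GAF output and for segment-level node sets).

A **global alignment without recombination** of a query s (length n)
against the graph is a global alignment of s against the spelling λ(p) of
one distinguished path p.  Because a path of a DAG visits each vertex at
most once, the per-path score table factorises into an ordinary
Needleman–Wunsch table: M[t, i] is the optimal score of aligning the
t-character prefix of λ(p) against s[:i], with

    M[t, i] = max( M[t−1, i] − g,             consume the path character
                   M[t, i−1] − g,             consume the query character
                   M[t−1, i−1] + d(λ_t, s_i) )  pair them

where d is +m for a match and −m̄ for a mismatch, and gaps are linear
(−g per gap column).  The backward table R[t, i] mirrors this for the path
suffix starting at labelled position t against the query suffix s[i:]; it
is filled by the same recurrence run right-to-left and bottom-up.  The
recombination-free optimum is max_p M_p[|p|, n].

A **recombination** is a switch from one path p1 to a different path p2 at
a junction (ρ, ψ), ρ on p1 and ψ on p2, possibly through a *virtual arc*
(ρ, ψ) absent from the graph.  The aligned walk is literally the
concatenation of a prefix of p1 ending at ρ and a suffix of p2 starting at
ψ.  When ρ = ψ the two halves share the junction vertex and its label
appears in both; we keep that literal semantics (the vertex occurs twice
in the emitted walk, as a (v, v) virtual junction), because it is the only
reading under which the traceback re-scores exactly to the dynamic-program
value.

The recombination cost is affine in the *displacement*.  Anchor the
junction in the smallest bubble containing it: α (branching vertex) is the
deepest vertex common to both paths that strictly precedes ρ on p1 and ψ
on p2; β (consolidating vertex) is the shallowest common vertex strictly
following both.  With a1 = α..ρ on p1, a2 = α..ψ on p2, b1 = ρ..β on p1,
b2 = ψ..β on p2 (vertex counts inclusive of both endpoints),

    d_r = | |a1| − |a2| + 1 | + | |b1| − |b2| − 1 |

and the total penalty is d_o + d_r · d_e.  The ±1 terms account for the
junction adding one position after ρ and removing one before ψ; a
perfectly balanced switch (e.g. between equal-length bubble branches at
corresponding offsets) costs only d_o.  A junction at the source (sink)
has no strictly-preceding (following) common vertex; α (β) then falls back
to the source (sink) itself.  Vertex counting conventions shift absolute
d_r values but cancel in comparisons; we fix the inclusive convention and
apply it consistently in the aligner and in all oracles.

The **recombination-aware optimum** combines the two passes:

    max( max_p M_p[|p|, n],
         max_{p1≠p2, v∈p1, w∈p2, j∈window}
             M_p1[v, j] + R_p2[w, j] − d_o − d_e·d_r(p1, p2, v, w) )

where j is the breakpoint (prefix s[:j], suffix s[j:]) constrained to a
centred window (fraction f of the query; f = 0.95 reproduces a
middle-95% restriction, f = 1 disables it; the bounds are
j ∈ [⌈n(1−f)/2⌉, ⌊n(1+f)/2⌋]).  An exact tie between the two branches is
resolved in favour of no recombination (parsimony).  Among equal-scoring
recombinations the tie-break is: smallest j, then smallest (v, w) in
topological order, then path-pair order — output is deterministic.

### Search strategy

The displacement of every junction is tabulated per ordered path pair with
one parallel scan: common vertices occur in the same relative order on
both paths (acyclicity), so nearest-common-before/after indices per
position give α and β in O(1), and the full |p1| × |p2| displacement
matrix is assembled with vectorised arithmetic.  The combination step then
iterates over ordered distinct path pairs and breakpoints, adding the
per-pair displacement matrix to the outer sum of an M column and an R
column.  Iterating over explicit path pairs — rather than keeping only the
per-vertex argmax and runner-up paths — matters for exactness: the
displacement term depends on which pair is chosen, so a pair that is not
among the top two by M + R can still win after the penalty.  The
best/second-best summaries are nonetheless maintained (and exposed via
`enforce_distinct_paths`) since they answer the distinct-path
maximisation at single cells in O(1).  Complexity is
O(|P|·|V|·n + |P|²·|V| + |P|²·B·n_w) for B the largest pair-matrix size
and n_w the window width — minutes at gene scale, which is the intended
regime (a production mapper would embed this as the exact inner step of a
seed-and-extend pipeline).

### Numerical choices

Scores are float64.  With integral match/mismatch/gap values every M and R
entry is an exact integer in floating point, so the traceback's equality
tests against the recurrence and all oracle comparisons are exact; the
displacement multiplier (default 0.1) enters only the junction penalty and
is accumulated in one fixed order everywhere (implementation and oracle
alike), so cross-checks compare identical bit patterns.  Penalties are
stored as nonnegative magnitudes and subtracted.  Characters outside
{A, C, G, T} are kept verbatim and match only themselves.  Traceback
prefers match/mismatch over consuming a path vertex over consuming a query
character.

## Scoring defaults

| parameter | symbol | default | role |
|---|---|---|---|
| match score | m | 2 | added per matching column |
| mismatch penalty | m̄ | 4 | subtracted per mismatching column |
| gap penalty | g | 4 | subtracted per gap column (linear) |
| recombination open | d_o | 4 | subtracted once per junction |
| recombination extend | d_e | 0.1 | subtracted per displacement unit |
| breakpoint window | f | 0.95 | centred query fraction admitting a junction |

These defaults reproduce the simulation configuration the method was
evaluated under; raising d_o (e.g. to 28) suppresses spurious junctions
supported by few variants, and the count of reported recombinations is
provably non-increasing in d_o for a fixed input set (branch 2b decreases
pointwise while 2a is constant).

## Synthetic data

`simgen.make_graph` emulates a per-gene bacterial pangenome: a random
backbone split into chunks, with a biallelic bubble at each of
`n_variant_sites` junctions — a SNP, or with probability `indel_fraction`
a 1–3 bp presence/absence indel — and `n_paths` strains carrying one
allele per site (allele columns non-constant; strain allele vectors
pairwise distinct when the site count allows).  Recombinant queries take a
prefix of one strain and a suffix of another, cut at a shared vertex whose
prefix length falls in a central window (default the middle 10–90%), so
every simulated query corresponds to a valid mosaic walk; ground truth
records the parent pair, the cut coordinate, the mosaic vertex set and the
*variant-free window* — the interval of cut coordinates spelling the same
query, within which the junction is mathematically unidentifiable.  Point
mutations are substitutions only, independent per base, always to a
different base.

Default study conditions (chosen once, as a desk-scale analogue of
per-gene graphs built from real strain sets): 5 strains, 10 variant sites,
160 bp backbone, 25% indel sites; recovery experiments use 100
mutation-free recombinants plus 20 non-recombinant controls, and the
oracle-equivalence suites use 200 (no-recombination) and 100
(recombination) randomised instances capped at 8 paths / 200 canonical
vertices / 100 bp and 6 paths / 150 vertices / 80 bp respectively.

For recovery experiments, draws are screened for *identifiability*
(`sample_identifiable_recombinant`): the true parent pair must be the
unique two-path mosaic explanation of the query, and every single strain
must be ≥ 2 edits away from it.  The second condition is not cosmetic:
under the default penalties a strain one gap away from the query ties the
mosaic score exactly (one gap column costs 4 = d_o), so such draws are
genuinely undecidable and no exact method can be expected to call them.

What the generator does *not* emulate: realistic topology from
graph-construction tools (nested or overlapping bubbles, shared long
deletions), multiallelic sites, indel mutations in queries, sequencing
error profiles, and the deep divergence of real gene variants.
Consequently, passing the recovery suite shows the method is exact and
well-behaved under its own model assumptions — not that detection
sensitivity on real, noisier pangenomes reaches the same rates.

## Reported quantities

The recovery study reports the fraction of mutation-free mosaics detected,
the parent-pair accuracy, the node-set Jaccard between the aligned walk
and the true mosaic walk, and breakpoint localisation *relative to the
variant-free window*: the deterministic tie-break parks the reported cut
at the window's left edge, so the raw offset from the simulated coordinate
measures the window geometry of the simulation (tens of bp at this gene
scale and variant density) rather than the aligner; the within-window rate
and the error beyond the window are the quantities the method actually
determines.

## Known limitations

- At most one recombination per alignment; a query mosaicking three or
  more donors is explained by the best single junction.
- Global alignment only: queries are assumed to span the gene
  source-to-sink; no semi-global or local mode.
- Linear gap penalties; no affine gap model.
- Forward-orientation GFA only (acyclic, +/+ links); no reverse
  complements, W-lines or GFA2.
- The O(|P|²·B·n_w) combination pass is quadratic in path-pair count and
  in pair-matrix size; whole-genome graphs are out of scope.
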