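# Methods

## The datastore and its assumptions

All analyses run against a directory of TSV tables and FASTA files
(organisms with semicolon-joined lineages, genes, pairwise homology hits
with a Smith–Waterman score and an identity fraction, domain annotations,
CDS and protein sequences keyed by gene id). The hit table is taken as
given — the package never computes similarity scores from raw sequences; it
plays the role the pairwise-comparison tables of an annotation service play
online. Loading validates every cross-reference and type invariant;
`validate_datastore` reports violations without raising, and accepts exactly
the datastores `load_datastore` accepts. A trailing stop codon on a CDS is
trimmed on load, so in memory `len(nt) == 3·len(aa)` always holds.

## Taxonomy and the age index

The taxonomy is the merged prefix tree of the organism lineages: root depth
0, child depth parent + 1. Taxon names are assumed globally unique — a name
implying two different parents is a construction error. No rank
normalization is attempted: depth counts whatever levels the lineage strings
contain, and organisms of unequal lineage length coexist naturally because
the LCA is found on the merged tree.

The PAI of a reference-organism gene is the minimum, over ortholog-bearing
organisms, of the LCA depth with the reference — equivalently the deepest
reference-lineage node ancestral to every such organism (the equivalence is
property-tested on random trees). Conventions:

* Orthologs are the genes surviving homology filtering that belong to
  organisms *other than* the reference; paralogs in the reference organism
  never age a gene.
* A gene with no ortholog outside the reference gets PAI = N, the terminal
  depth — the youngest age the scale can express.

Adding an ortholog organism can only lower (never raise) the PAI, and
raising the identity threshold can only raise it; both laws are tested.

## Homology filtering and clustering

Hits are kept when `sw_score ≥ sw_min` **and** `identity ≥ identity_min`
(inclusive bounds — the thresholds are read as minimum acceptable values).
Domain composition can further filter candidates:

* *simple*: domains are ranked by how many candidates carry them
  (descending count, ties lexicographic for determinism); a candidate must
  contain all of the first `T` ranked domains. `T = 0` keeps everything and
  `T` beyond the ranking length degrades to requiring the whole ranking.
* *detailed*: a candidate must carry at least one of the user-listed
  domains. The rule is read literally — "lacking *any* of them" deletes; a
  stricter contains-all variant would be a one-line change but is not the
  default reading.

Network genes linked by a surviving hit in either direction (the similarity
relation is symmetrized) form homology clusters — connected components of
that graph; genes with no qualifying link are singletons. Collapsing
replaces each cluster by one node carrying its member list, re-wires edges,
merges duplicates and drops intra-cluster self-loops. Cluster count is
non-increasing as thresholds are lowered, and collapsed networks preserve
reachability between clusters.

## Divergence (Ka/Ks)

The nearest ortholog is the one whose organism has the deepest LCA with the
reference; taxonomic distance for the optional `max_dist` cutoff is
`N_ref − lca_depth` (lineage levels between the reference terminal and the
divergence node). Ties are broken by organism code then gene id so results
are reproducible. An optional whitelist restricts the search to named
organisms (e.g. the closest-primates set for human references).

Proteins are aligned globally with BLOSUM62 and affine gaps: a gap run of
length L costs `11 + 1·L`, terminal gaps included. Among co-optimal
alignments the aligner's canonical first alignment is used — deterministic,
though the specific tie-break order is an implementation choice; the score
itself is verified optimal against exhaustive enumeration. Codons are then
threaded through the protein alignment (gap columns become `---`), with
every codon checked against its residue under the standard code.

Ka and Ks use the Nei–Gojobori (1986) method:

* Per codon, the synonymous site count is the fraction of its nine
  single-nucleotide neighbors that preserve the amino acid, each position
  contributing (synonymous changes)/3. Changes that create a stop codon are
  counted as nonsynonymous. Site totals are averaged over the two sequences.
* Differences for codon pairs differing at 2–3 positions are averaged with
  equal weight over all minimal substitution pathways; pathways passing
  through a stop codon are excluded (if all are blocked, all are used — a
  degenerate case that cannot arise in the simulator's stop-free output).
* Columns containing a gap or stop codon are excluded entirely.
* `pN = Nd/N`, `pS = Sd/S`, and `d = −(3/4)·ln(1 − (4/3)p)` (Jukes–Cantor).
  Status is `saturated` when either p ≥ 3/4 (the correction diverges),
  `undefined_ks_zero` when no synonymous difference was observed (the ratio
  is undefined; Ka is still reported), otherwise `ok` with DI = Ka/Ks.

The estimator is symmetric under sequence swap. NG86 was chosen as the
classical, fully specified counting method; LWL85/YN00/ML variants are
extension points, not implemented. The `method` column in `di.tsv` records
the estimator. Because the alignment parameters and the counting method are
package choices, numeric parity with any particular external Ka/Ks tool is
not guaranteed.

## Network statistics

Gene Set PAI is the plain mean. Network PAI is `Σ(PAI·d) / (2·N)` with `d`
the gene node's degree in the *full* network — edges to compound or map
nodes count, because pathway graphs often wire genes through compounds —
while `N` counts gene nodes only (non-gene nodes carry no PAI and must not
dilute the denominator). The formula is applied literally; note it is not
bounded by the maximum PAI on high-degree networks (a k-regular gene-only
network gives exactly `(k/2) ×` Gene Set PAI, which the tests exploit as a
closed form). The median taxon uses the lower middle value on even counts
so the reported taxon is always an attained PAI.

Phylogenetic profiles list, for each network gene, the organisms carrying
at least one ortholog (`+`/`-` matrix, rows sorted by organism code,
columns in network gene order; no all-`-` rows).

Coloring min–max normalizes the values and interpolates piecewise-linearly:
heatmap anchors blue → cyan → green → yellow → red at 0, ¼, ½, ¾, 1 (old
genes blue, young red), diverging scheme blue → white → red at 0, ½, 1.
Constant input maps to the mid anchor. The ring layout places genes with
equal PAI on one circle, radius proportional to the *rank* of the PAI value
(not the raw value, so sparse PAI sets stay readable), with non-gene nodes
on separate outermost circles per type.

## Threshold sweeps and reports

A sweep re-runs ortholog detection and both PAI statistics over an identity
grid with all other settings fixed; per-gene PAI and Gene Set PAI are
non-decreasing along an increasing grid, which the tests assert as a law. At
identity 1.0 with no perfect hits every gene collapses to PAI = N.

Reports are static HTML with relative links and no JavaScript: a global
index page linking one page per network, each with the summary block, a PAI
histogram (one bin per integer PAI value), the sweep curve when available,
and the per-gene tables with the DI table sorted descending (undefined DI
last — candidate diversifying selection surfaces first). Every plot has a
sibling TSV holding its data. Rendering is pure presentation:
`timestamps=False` makes re-rendering byte-identical.

## The simulator: what it emulates, what it does not

`simulate_datastore` builds a world where the right answer is known:

* Taxonomy: a reference lineage of depth N = 14 by default (the human-
  lineage value) with side organisms attached so that for every depth b
  there is an organism whose LCA with the reference is exactly b.
* Ortholog presence is planted by clade membership, not sequence evolution:
  a gene born at level b gets ortholog genes exactly in organisms at levels
  ≥ b, always including one at the boundary level b, the rest sampled at
  `ortholog_density` (default 1.0, which makes the birth level exactly
  recoverable). Hit scores are drawn above the default thresholds
  (SW ∈ [600, 1500], identity ∈ [0.6, 0.95] against defaults 500 / 0.5).
* Codon pairs: a random stop-free ancestral CDS (default 100 codons for the
  datastore, 300 for rate-recovery experiments) mutated with planted
  synonymous and nonsynonymous substitution counts — the target rates
  (defaults Ka = 0.05, Ks = 0.2, a typical purifying-selection regime)
  inverted through the Jukes–Cantor map and multiplied by the ancestral
  NG86 site counts. At most one substitution per codon, so pathway
  averaging classifies every difference exactly as planted.

All randomness flows through one seeded `numpy.random.Generator` (PCG64);
identical seeds reproduce identical tables, sequences and networks across
platforms.

Deliberately *not* emulated: among-site rate variation, indels in coding
pairs, multiple hits per codon, horizontal transfer, unequal lineage
sampling biases, and realistic score/identity distributions. Passing tests
on this world therefore demonstrate the correctness of the computations —
LCA depths, counting, formula evaluation, monotonicity — not robustness of
the biology to noisy real-world homology detection.

## Numerical and interface choices

* All thresholds inclusive; all tie-breaks lexicographic; all row orders in
  output files deterministic.
* Alignment scores are exact floats from integer matrix entries; NG86
  agreement with the independent enumeration oracle is asserted to 1e-9.
* Saturation is declared at p ≥ 3/4 before taking the logarithm; values
  near the boundary are numerically meaningless and flagged rather than
  reported.
* Problem sizes in the test-suite experiments (200 enumeration pairs of
  length ≤ 6, 100 rate-recovery pairs of 300 codons, 50 planted genes) were
  chosen to make the checks statistically meaningful while keeping the
  default suite fast to run.

## Known limitations

* One reference organism per analysis; cross-reference comparisons require
  separate runs.
* The NG86 estimator is undefined when no synonymous difference is observed
  and unreliable near saturation; status flags make this explicit instead
  of imputing values.
* Domain-based filtering operates on the candidate set of the gene (or the
  network's candidate set when clustering); with very sparse domain
  annotations the simple mode degenerates to keeping everything.
* The HTML report is intentionally minimal — no interactivity, no export
  formats beyond the TSV data files.
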