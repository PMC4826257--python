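# Methods

## The comparison

`consurvey` asks whether one gene set (the "targets", e.g. FDA-approved
drug-target genes) is more evolutionarily conserved than a control set
("non-targets"), combining three classical evolutionary features with
four network-topology features:

* **Evolutionary rate** ω = dN/dS per (gene, species), from a
  BioMart-style orthology table restricted to one-to-one orthologs with
  both rates present and dS > 0. ω < 1 indicates purifying selection;
  lower ω means stronger conservation.
* **Conservation score**: the raw optimal Smith–Waterman local-alignment
  score between the human protein and its species ortholog, BLOSUM62,
  affine gaps (open 11, extend 1, a length-L gap costing 11 + L).
* **Ortholog percentage**: the fraction of the gene set with a
  one-to-one ortholog in a species, × 100. The denominator is the whole
  gene set, not the annotated subset, so the feature measures ortholog
  retention of the set as defined.
* **Topology** of an undirected PPI network: degree, clustering
  coefficient 2e_v/(k(k−1)), betweenness normalized by (n−1)(n−2) over
  ordered pairs (Brandes' algorithm), and per-node average shortest
  path length (mean BFS distance to reachable nodes).

The statistical scheme has two levels. Within each species (or within
the network), the two sets' per-gene values are compared by a two-sided
Wilcoxon rank-sum test with midranks, normal approximation, tie
correction and continuity correction — group sizes are in the hundreds
to thousands, where the normal approximation is accurate and exact
enumeration infeasible. Across the species panel, the per-species
group medians are paired and compared by a Wilcoxon signed-rank test.

## The control set

Non-targets are derived by whole-family exclusion from a Pfam-style
gene → family map: a gene qualifies only if its entire family
annotation is disjoint from the union of families containing any target
gene. Two conservative choices: genes without any family annotation
are ineligible (domain dissimilarity cannot be certified), and
exclusion is triggered by any shared family rather than a count
threshold. Both are deliberate readings of "no similar domains";
clan-level exclusion is out of scope.

## Cross-species test variants

The signed-rank test drops zero differences (Wilcoxon's original
treatment), uses midranks on |d|, and offers two modes:

* **exact** — the full permutation distribution of W+ over the 2ⁿ sign
  assignments, computed by convolution; refused when |d| values tie
  (the distribution conditional on midranks is then nonstandard, and R,
  whose `wilcox.test` this mirrors, falls back the same way);
* **normal_approx** — mean n(n+1)/4, variance n(n+1)(2n+1)/24 with an
  optional tie correction Σ(t³−t)/48, and a 0.5 continuity correction
  toward the mean. Two-sided p = 2·min(tails), capped at 1.

The pipeline's cross-species default is the normal approximation with
continuity correction and **without** tie correction. On 21 median
pairs that all favor one group (W+ = 0), this gives
p = 6.41×10⁻⁵, and exact mode gives 2¹⁻²¹ ≈ 9.54×10⁻⁷ — the two
headline magnitudes of this analysis design. The ortholog-percentage
comparison uses exact mode (n = 21 pairs, continuous enough in
practice at realistic set sizes to be tie-free).

A note on relative accuracy: the normal approximation tracks the exact
p within a few percent in the moderate range (p ≳ 0.05) but deviates
by factors of 2–3 in the far tail (p ~ 10⁻⁴); agreement checks in the
test suite are therefore scoped to the moderate range.

## Alignment engine

Conservation scores use Biopython's `PairwiseAligner` in local mode —
an exact Smith–Waterman, not the heuristic BLASTP it stands in for.
Exact local alignment is deterministic and oracle-verifiable; its
score is an upper bound on a BLASTP raw score under the same scheme,
a systematic (and for a two-group comparison, direction-neutral)
difference. The score is the raw integer score of the single best
local alignment; the empty alignment is admissible, so scores are ≥ 0.
The BLOSUM62 distributed with Biopython scores the unknown residue X
as 0 against every standard residue and −1 against X. E-values, bit
scores and multiple HSPs are out of scope.

## Synthetic study generator

The generator emulates every input of the comparison with planted
group effects; its defaults are the study conditions used by the test
suite and the acceptance measurements.

| parameter | default | meaning |
|---|---|---|
| n_targets / n_nontargets | 300 / 900 | set sizes (≈ 1:3, scaled down ~4.5× from a realistic 1347/4181 study) |
| species | 21-code panel | mammalian species panel |
| omega_logmean (target / non-target) | log 0.10 / log 0.13 | log-normal ω medians e^μ = 0.10 vs 0.13, matching realistic median dN/dS |
| omega_logsd | 0.8 | log-scale sd; reproduces the ~3.3× IQR/median spread of real per-gene ω |
| ds_logmean, ds_logsd | log 0.5, 0.4 | synonymous-rate distribution, shared between groups |
| ortholog_prob (target / non-target) | 0.9 / 0.75 | per-species one-to-one presence probability |
| one2many_prob | 0.05 | chance of a one-to-many row when no one-to-one is emitted |
| missing_rate | 0.02 | rows with an empty dN or dS field, to exercise the non-null filter |
| seq_len_range | (80, 200) | protein lengths; short enough to keep ~12 000 alignments cheap |
| divergence_scale | 2.0 | per-site substitution probability min(0.95, 2ω): ω = 0.10 → 20% divergence, a plausible mammalian ortholog distance |
| sequence_species | first 5 codes | alignment runs on a 5-species subset (the expensive stage) |
| degree_weight (target / non-target) | 3.0 / 1.0 | Chung–Lu degree propensities |
| mean_degree | 8.0 | average network degree (HPRD-like density) |
| triad_closure_prob | 0.2 | chance of closing one neighbor pair per target node, raising target clustering |
| n_families, family_overlap | 150, 0.1 | family pools; fraction of non-targets planted into target families |

Design choices worth noting:

* dN is simulated as ω·dS rather than independently, so dN/dS recovers
  the planted ω exactly — parameter recovery is an identity, not an
  estimate.
* Substitutions are uniform over the 19 alternative residues, not
  BLOSUM-biased; the conservation score still decreases monotonically
  in divergence on average, which is all the comparison needs.
* Each sub-generator (orthology, sequences, network, families) draws
  from its own stream spawned from the master seed, so changing one
  component's size never perturbs another's output.
* Sequence pairs are generated for one-to-one rows whose dN and dS are
  both present (ω is then recoverable from the row itself); the 2% of
  rows with an injected missing value get no pair.
* Outputs are written in sorted order with fixed float formatting, so
  identical configs produce byte-identical files.

What the generator does **not** emulate: phylogenetic structure among
the 21 species (each species is drawn independently — no tree, no
correlated rates), codon-level evolution, indels, protein domain
architecture, and the degree–conservation correlations of real PPI
data. Passing tests therefore demonstrate that the pipeline recovers
planted effects of realistic magnitude under clean sampling
assumptions — not that the biological findings themselves would
replicate on a new database release.

## Numerical and degenerate-input conventions

* Quartiles are type-7 (linear interpolation of order statistics), the
  numpy/R default, matching the summary-table convention.
* Zero-variance rank tests (all values identical) return p = 1; a
  signed-rank test with no nonzero differences is an error.
* dS = 0 rows are excluded from ω (the ratio is undefined); dN = 0
  with dS > 0 yields ω = 0 and is kept.
* Betweenness normalization divides by whole-graph (n−1)(n−2) even on
  disconnected graphs (single-n formula, literal reading); pairs with
  no connecting path contribute 0. Graphs with n < 3 are rejected.
* ASPL is the mean distance from a node to the nodes reachable from
  it; it is NaN for isolated nodes and those nodes are excluded from
  the topology comparison. (The name "average shortest path length"
  is sometimes glossed as paths *through* a node; the implemented
  per-node closeness-style mean-distance metric is the standard
  Cytoscape node attribute and is what "how tightly a node is
  connected" measures.)
* Report tables print medians/quartiles with 4 decimals and p-values
  in 3-significant-digit scientific notation.

## Problem sizes

The default synthetic study (300 + 900 genes, 21 species, 5 alignment
species, ~4 800-edge network) runs the full pipeline in well under a
minute; the null-calibration sweep uses 400 seeds of the
orthology-only path. These sizes were chosen so planted effects of the
configured magnitude are recovered with wide margin while the whole
suite stays cheap to run routinely.

## Known limitations

* The exact signed-rank mode refuses tied |differences| rather than
  enumerating the midrank permutation distribution; at the scaled-down
  default set sizes the ortholog percentages (granularity 100/300 and
  100/900) tie often, so the pipeline's percentage test then reports
  the normal-approximation fallback. The exact enumeration over sign
  assignments with midranks is available as a separate computation in
  the acceptance script.
* The conservation stage compares 5 species, so its cross-species
  signed-rank test has little power (minimum two-sided p = 1/16 at
  n = 5); the direction of the effect, not its cross-species p, is the
  meaningful output there.
* Smith–Waterman scores are upper bounds on BLASTP raw scores; absolute
  score magnitudes are comparable but not identical to a BLASTP
  pipeline's.
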