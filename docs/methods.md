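# Methods

## Scope and model

`citefronts` detects research fronts in a publication corpus by direct-
citation clustering. The model assumptions are:

- Citation links carry the community signal. Direction is irrelevant for
  cohesion, so the network is undirected and unweighted; a paper pair is
  linked once regardless of who cites whom or whether both cite each other.
- Only within-corpus citations count. A reference whose id is not in the
  corpus is ignored, so the node universe — and the N against which all
  percentages are computed — is exactly the retrieved set.
- The largest connected component is the analysis universe. Smaller
  components are typically disconnected singletons or tiny cliques with no
  interpretable front structure; they are excluded before clustering, and
  the retained share is reported (`lcc_fraction`, half-up to one decimal).
- A research front is a modularity community. Clusters are communities of
  the LCC under Newman modularity at resolution γ; sub-fronts are
  communities of a cluster's induced subgraph.
- Cluster-characteristic vocabulary is what TF-ICF retains: frequent inside
  one cluster, absent from most others. No stemming, embedding or manual
  curation is applied.

## Louvain implementation

Modularity is maximized with the standard two-phase heuristic: local
moving (each node greedily joins the neighboring community with the largest
gain) followed by aggregation of communities into weighted super-nodes with
self-loops, repeated until a pass makes no move or `max_passes` (default 50)
is reached. The per-pass modularity trace is kept on the returned partition
(`q_history`) and is non-decreasing by construction.

Reproducibility requires pinning every free choice the classic algorithm
leaves open:

- **Visit order** — a uniform shuffle of the (super-)nodes from
  `random.Random(seed)`, re-drawn each local-moving round.
- **Tie-breaking** — candidate communities whose gains are within
  `min_move_gain` (default 1e-12, which also absorbs floating-point noise
  and prevents oscillation) of the best are tied; a tie retains the current
  community, otherwise the community with the smallest label wins. A
  community's label is the smallest node id it contains; aggregation names
  each super-node after its smallest original member, so labels stay
  comparable across passes.
- **Ranking** — final communities become clusters "1", "2", … by descending
  size, ties by smallest member id; sub-clusters of parent P are "P-1",
  "P-2", … by the same rule.

Isolated nodes (possible in induced subgraphs) each form their own
community and never enter gain computation. Equivariance under node
relabeling holds for order-preserving relabelings (the seeded visit
protocol then sees the same order); an arbitrary relabeling may select a
different, equally valid local optimum.

`exhaustive_best_partition` enumerates all set partitions (Bell-number
search, capped at 12 nodes) and returns the global optimum; tests bound the
heuristic by it on every connected graph with ≤ 6 nodes and check equality
on separable fixtures (disjoint cliques), plus the closed-form values
Q(two triangles, planted) = 1/2, Q(one community) = 0,
Q(single edge, singletons) = −1/2.

## Tokenization and TF-ICF

Text scored is title + abstract (joined with a sentence break). Sentences
are split on `.!?;` and newlines; words are lowercased, NFKC-normalized,
punctuation-stripped (internal hyphens kept by default, so "pd-1"
survives); stopwords (a small built-in English list, replaceable) and
tokens shorter than `min_token_len` (default 2) are removed *before* n-gram
formation; contiguous 1..`ngram_max`-grams (default 3) are emitted within
sentence boundaries, which is how multi-word keywords such as "immune
checkpoint inhibitor" arise.

TFICF(i, j) = tf_ij · ln(N / cf_i) with tf a raw count and N the number of
clusters. Two deliberate choices:

- **N = clusters.** The score's name and behavior ("inverse cluster
  frequency", offset by the number of clusters containing the word) are
  internally consistent only with cluster counting; an alternative
  sentence-count denominator is available as `icf_n_mode="sentences"` for
  fidelity experiments. Rankings within a cluster are unaffected by the
  choice of N (it shifts all of a term's scores by the same log factor only
  when cf is fixed; across terms it is monotone), but absolute scores
  differ.
- **No length normalization.** tf is a raw count, so absolute scores grow
  with cluster size; this is a documented bias, irrelevant to within-
  cluster rankings, which are the reported object.

Natural log throughout; rankings are base-invariant. Ties in keyword rank
break alphabetically.

Query filtering (`immun* AND t lymph*` style) matches AND-ed clauses
against the raw title+abstract token stream — without stopword or length
filtering, since queries legitimately contain single-character tokens like
"t" — with `*` as plain token-prefix match and multi-word clauses requiring
contiguous token runs. PubMed's stemming and MeSH expansion are not
emulated: the original engine-side query is irreproducible locally, and
deterministic semantics matter more here than recall parity.

## Reporting

Profiles carry rank, size, average year and top-k keywords (default 20).
Average year is the arithmetic mean over members with a known year
(computed exactly in decimal), rendered half-up to an integer in tables
while the full-precision value is kept in JSON output; records without a
year are excluded from the mean and logged. Coverage of the top-k clusters
uses the clustered (LCC) node count as denominator and rounds half-up to
one decimal. Sub-clustering triggers for clusters holding ≥ 10% of LCC
nodes (`subcluster_min_frac`); child keyword profiles are scored among the
children of their own parent (N = number of children), so a child's
keywords are what distinguishes it from its siblings, and child rows are
reported beneath their parent with within-parent ranks.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
citation-dense fronts with distinctive vocabularies — as a planted
partition: each unordered node pair is linked independently with
probability `p_in` within a block and `p_out` between blocks; each link
becomes a citation from the younger paper to the older (ties: larger id
cites smaller), which the graph stage then discards, exercising the
undirected conversion. Abstracts are shuffled bags of terms with Poisson
counts: mean `signature_rate` per signature term of the record's own block
(disjoint across blocks), mean `background_rate` per shared background
term. Years are uniform in per-block windows. All draws come from one
`numpy` generator in a fixed order, so a config is byte-reproducible.

Defaults are the benchmark regime: 5 blocks × 40 papers, p_in = 0.15
(expected within-block degree ≈ 5.9), p_out = 0.005 (between-degree ≈ 0.8),
3 signature terms per block at mean 4 occurrences per abstract, 50
background terms at mean 1, staggered 10-year windows. This regime is
separable but not trivial — the graph is sparse, blocks are small enough
for occasional boundary errors, and background vocabulary dominates
abstracts by volume — so recovery (ARI ≥ 0.9 in ≥ 19/20 seeds, mean top-1
keyword recovery ≥ 0.9) is an end-to-end check of the whole chain, not a
formality. A 20-run benchmark takes a few seconds.

What the generator does **not** emulate — and hence what passing tests do
not establish about real corpora: realistic citation-age and degree
distributions (no preferential attachment), topic drift over time,
overlapping or nested fronts, natural-language syntax (bags of terms have
no grammar, so n-gram keywords beyond unigrams are much weaker than in real
abstracts), and entity-resolution noise (duplicate or retracted records).

## Pipeline and determinism

`run_pipeline` composes: read → optional query filter → graph → LCC →
Louvain → rank → sub-cluster large clusters → term stats → TF-ICF →
profiles → coverage → artifacts (partition TSV with hierarchical labels,
keyword TSV, TSV/Markdown reports, full-precision JSON profiles, manifest).
A stage failure aborts with the stage name and cause. All randomness flows
from one top-level seed via stage-keyed child seeds (SHA-256 of
`"<seed>:<stage>"`, truncated below 2^31), and artifacts are byte-identical
across reruns with the same config; the manifest records a hash of the
analysis-relevant config.

The acceptance script runs the benchmark at the defaults above with 20
seeds derived from its `--seed`, plus one full pipeline run on a 200-paper
corpus — sizes chosen to exercise every stage while keeping the whole
script in seconds.

## Known limitations

- Louvain is a heuristic: it can split or merge planted blocks near the
  detectability threshold, and is subject to the resolution limit (small
  communities may be absorbed at γ = 1; γ is exposed).
- The cluster count of a real corpus depends on γ and the corpus snapshot;
  no post-hoc merging of tiny communities is performed.
- Raw-count tf favors large clusters in absolute score; compare scores only
  within a cluster.
- TSV corpora rely on `csv` quoting for embedded tabs/newlines; the
  canonical interchange format is JSONL.
- The local query matcher is deliberately weaker than PubMed's (no MeSH,
  no stemming): result sets will differ from engine-side retrieval.
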