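# Methods

## The screening problem

Given (i) a table of known TF→target regulatory relations, (ii) a
collection of functional gene sets, and (iii) a gene-level expression
matrix from a two-strain (case/control) time course, `netscreen` asks, for
every candidate regulatory network, strain and time window: *is this
network's wiring consistent with the observed expression of its member
genes, and are its genes over-represented among the differentially
expressed ones?* Networks passing both filters are called **active**;
networks active in exactly one strain within a window are **differentially
active** and are the disease-candidate output.

## Candidate (reference) networks

Each gene set defines one candidate: every relation whose **target** gene
belongs to the set is collected, and if at least one relation matches, the
collected relations form a directed network named after the set (TFs enter
as nodes regardless of their own membership; TF membership alone pulls in
nothing). The likelihood model below requires a DAG; relation tables can
contain cycles, so construction optionally breaks them by removing the back
edges of a deterministic depth-first traversal (lexicographic root and
successor order), logging each removal. Strict mode raises instead.
Networks are restricted to genes present on the array; fewer than
`min_nodes` (default 3) surviving nodes, or zero surviving edges, produces
a recorded skip rather than a score, since the empirical null of a 2-node
network is nearly degenerate.

## Gaussian-network log-likelihood

For a DAG G over genes X_1..X_n with expression measured at m samples, the
joint density factorizes by parentage:

    f(X_1, ..., X_n) = ∏_i f(X_i | pa{X_i})

Each conditional is modelled as linear-Gaussian,
X_i | pa{X_i} ~ N(β_0 + Σ_j β_j pa_j, σ_i²), fitted per node by ordinary
least squares; the residual variance is the maximum-likelihood estimate
σ̂_i² = SSR_i/m. Substituting the MLE into the Gaussian log-density gives
the closed-form per-node contribution

    ll_i = −(m/2) · (ln(2π σ̂_i²) + 1),

and the network score is ll(G) = Σ_i ll_i. The MLE denominator m (rather
than m−1 or m−n_i−1) keeps the score a genuine maximized log-likelihood;
because the GCP below is rank-based and the null networks are scored
identically, the denominator choice does not affect screening decisions.

Numerical choices:

* **Rank deficiency.** With m as small as 5 and unbounded in-degree in null
  draws, designs with n_i + 1 ≥ m occur; they are solved by the
  minimum-norm pseudoinverse (`numpy.linalg.lstsq`) with no ridge penalty.
* **Variance floor.** A perfectly interpolating fit would give σ̂² = 0 and
  an infinite score; σ̂² is floored at max(1e−12, 1e−8 · var(child)).
  Floored fits get large but finite contributions, so interpolating null
  networks can out-score a genuinely matching network — this is the
  dominant (and intended, absent any penalization) small-m behaviour and
  the reason the single-week segment is the hardest cell of the design.
* **Ties** in log-likelihood count as "not larger" in the null comparison
  (strict inequality), so exact ties never penalize the tested network.

## Graph consistency probability (GCP)

A raw log-likelihood has no absolute scale, so it is referred to an
empirical null of N_r random networks sharing the tested network's node and
edge counts, fitted on the same samples:

    GCP = N_s / N_r,   N_s = #{null networks with strictly larger ll}.

Default N_r = 2000 (reducible in config; the acceptance runs use 200–500),
significance at GCP ≤ 0.05. The default null (`random_dag`) draws node
labels uniformly from all measured genes, imposes a uniformly random total
order and samples order-respecting edges — a DAG by construction with
exactly the required counts. A topology-preserving alternative
(`label_permutation`) relabels the tested network instead; it is stricter
in that it controls for the tested topology's intrinsic fitting capacity.
The tested network's own node set is not excluded from draws (exclusion
would bias the null). Under exchangeability (i.i.d. data, tested network
itself a null draw) the GCP is uniform on {0, 1/N_r, …, 1}; the calibration
test checks both the 5% tail mass and a 10-bin χ² uniformity fit.

## Expression signature and enrichment

Per time window (weeks pooled), each gene is tested case vs control with
the classical pooled-variance two-sample Student's t (two-sided; genes
constant in both strains are reported t=0, p=1 and never significant), and
the Benjamini–Hochberg step-up controls FDR at q = 0.05. The signature M is
the set of rejected genes intersected with the reference universe N (the
union of all candidate-network genes measured on the array). A network with
k genes in the universe, l of them in the signature, is scored by the
upper-tail hypergeometric probability

    p_enrich = P(X ≥ l),  X ~ Hypergeom(N, M, k),

with p_enrich = 1 when l = 0. Enrichment is computed once per
(network, segment) — the signature is cross-strain, so both strains of a
cell share it, while GCP is strain-specific. Both filters at 0.05 define
the active flag.

## Pipeline determinism

Each (network, strain, segment) cell's null draws use a substream seeded by
SHA-256 of (master seed, network name, strain, segment label), so results
are independent of evaluation order and reruns are byte-identical. The run
manifest records parameters, input checksums and skip reasons.

## Combined dynamic graphs

Within a functional category (category assignments are analyst-supplied
data) and strain, active networks sharing at least one gene — transitively
— are merged; edges are the union of member edges, annotated with the
segments in which any contributing network was active, and node segments
are the union over incident edges. Nodes are typed TF / target / both by
degree, colored by their segment subset (early-only gray; early+middle
yellow; early+late purple; all red; middle "right-blue"; middle+late blue;
late green), and marked up/down when they belong to a relevant segment's
signature and their case mean exceeds/falls below the control mean over
those segments' samples. Graphs are emitted as GraphML (attributes
preserved; set-valued attributes serialized as sorted comma-joined
strings) and SIF.

## Synthetic data generator

The generator emulates the screening setting end to end: two strains ×
five ages (4, 8, 12, 16, 20 weeks) × five replicates, ages grouped into
{4}, {8,12}, {16,20}. Its structural choices:

* **Reference:** each TF regulates its own disjoint block of 3–10 targets;
  each gene set selects a random subset of one TF's targets. Every
  candidate is then a connected TF-centred star of 4–12 nodes, and any
  union of planted networks is automatically acyclic. Real regulons overlap
  and chain more than this; the benchmark keeps candidate independence
  interpretable (overlap still arises through sets sharing a TF's targets).
* **Background:** gene value = per-gene baseline (drawn once, shared by
  strains) + N(0, baseline_sd²), baseline_sd = 1.
* **Planted activity:** per (strain, segment), member genes of the planted
  networks are regenerated in topological order as
  child = 0.9 · Σ parents + N(0, 0.3²). Note a consequence checked by the
  tests: planting a network in one strain only also changes those genes'
  means relative to the other strain, i.e. single-strain activity induces
  differential expression by itself.
* **Planted DE:** chosen genes get a mean shift in the case strain within a
  segment (generator default 2.0 units).
* **Seeding:** every draw flows from the design seed through named
  substreams; no global random state.

### The standard benchmark

300 genes (25 TFs), 30 candidate networks; per segment 3 networks are
planted active in the case strain only, plus one network active in *both*
strains at the middle segment as a control for the differential flag
(truly active, not differentially so). 25 DE genes per segment, drawn
first from the member genes of that segment's case-active networks (so the
enrichment filter has signal), padded with background genes of alternating
sign. The benchmark's DE shift is 3.0 within-strain standard deviations:
a design-time power calculation showed that at the single-week segment
(m = 5 per strain, 300 genes) the BH signature retains a 2-sd shift too
rarely (median signature ≈ 2–3 genes; planted networks pass enrichment in
only ~26% of datasets), whereas 3 sd yields reliable recovery at every
segment — the benchmark is meant to be detectable by a correct
implementation, and 3 sd is well within the range of strong microarray
effects.

What passing the benchmark does and does not show: it validates the
statistical machinery (calibrated null, power against planted structure,
FDR control, threshold logic, determinism) on data that satisfy the model's
assumptions exactly. It does not probe probe-level noise, normalization
artifacts, batch structure, heavy-tailed expression, correlated background
genes, or misspecified (non-linear, feedback) regulation — conclusions
about real arrays require the real data.

## Problem sizes used by the test and acceptance runs

GCP calibration: 200 trials × N_r = 200 on 50 genes, m = 10. GCP power:
100 trials × N_r = 500 (star of 7 nodes, coefficient 0.9, noise sd 0.3).
FDR: 500 simulations × 200 genes at 5 vs 5. Benchmark screening:
30 networks × 2 strains × 3 segments at N_r = 500; determinism checks at
N_r = 100. These sizes give stable Monte-Carlo estimates (binomial SE ≈
1.5% for the calibration tail) while keeping a full run under a minute
each.

## Known limitations

* The likelihood has no complexity penalty; with very small m the variance
  floor lets interpolating null networks dominate, inflating GCP for large
  dense candidates. A penalized or cross-validated score would trade
  faithfulness to the plain factorized-likelihood definition for small-m
  robustness.
* Only linear conditionals are implemented (no spline/non-linear
  regression); only mean-shift DE is planted.
* Ortholog mapping is a pure rename pre-pass; no symbol normalization is
  attempted.
* The hypergeometric universe N uses the measured reference-network gene
  union; other universe conventions (whole array, whole genome) change
  p_enrich systematically and are not offered.
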