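# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `myconet`, and what the synthetic test bed
does and does not establish about real data.

## Graph representation and resistance weighting

A mycelium is a spatially embedded undirected multigraph. Parallel
edges are kept (two hyphae genuinely can join the same node pair in an
extraction); self-loops are dropped with a logged warning. Node kinds
are `root`, `tip` (measured degree 1) and `junction` (everything else;
degree-2 chain nodes are normally dissolved during extraction, and
hand-built graphs that retain them are classed as junctions).

Edge resistance is `l / (w/2)^α` with the radius convention r = w/2
(widths are what images yield). α = 4 emulates Poiseuille flow through
a single hyphal tube (micro scale, µm units); α = 2 treats a cord as a
bundle whose conductance grows with hyphal number rather than tube
radius (macro scale, mm units). Resistance units are arbitrary but
consistent: every reported trait is a ratio or a mean of reciprocals,
so the scale cancels within a network.

The inoculum cannot be resolved into hyphae, so it is represented as
one Root node connected to caller-supplied boundary nodes by synthetic
edges with length = Euclidean distance and width = the maximum measured
width — a deliberately strong, non-limiting connection. Root edges are
part of the path graph (transport may pass through the inoculum) but
are excluded from every edge statistic, volume sum, edge count and
attack scheme. On edge-list load, endpoint coordinates within 1e-6
physical units are merged into one node; exported coordinates share a
provenance, so a tighter tolerance would only split true nodes.

## Traits

**Colony area** is the convex hull of the measured node coordinates —
parameter-free, at the cost of overestimating area for strongly
non-convex colonies (an alpha-shape would need a scale choice).

**Branching angle** uses the daughter–daughter convention: at each
junction the incident edge whose far endpoint is resistance-closest to
the Root is the parent; the angle between the two remaining (daughter)
chords — taken from the junction to each edge's first polyline waypoint
— is reported, and junctions of degree ≥ 4 contribute their minimum
pairwise daughter angle. The parent-daughter alternative would differ
systematically; the convention is recorded here because published
figures rarely state it.

**Meshedness** is the planar cycle density, rank of the cycle space
over the planar maximum: (E − N + C) / (2N − 5), counting measured
edges, their incident nodes, and the connected components C of the
measured subgraph. Writing the rank as E − N + C rather than E − N + 1
matters because the measured subgraph of a colony is typically a forest
of several trees that only the Root joins up: trees must score exactly 0.

**Efficiencies.** R_eff (RT_eff) is the mean of 1/d(root, i) over all
non-root nodes (over tips), with d the shortest-path resistance
distance; unreachable nodes contribute zero. G_eff averages 1/d(i, j)
over unordered non-root pairs; the Root is never an endpoint but its
edges may carry paths. G_eff is reported in ordinations as
G_eff/G_eff(MST) — the gain over the cheapest spanning backbone — since
the raw value scales with colony size. Note that the mean of
reciprocals is dominated by near pairs; this is inherent to the
definition, and the generator therefore never places distinct nodes
closer than one hyphal width (below that separation an image extraction
could not resolve them either).

**MST baseline.** Kruskal on the resistance weights with the
deterministic tie-break (resistance, length, edge id); root edges are
force-included first so the inoculum connection is identical in the
observed network and its baseline, making the G_eff and volume ratios
pure measures of measured structure. Volumes use the cylinder
π (w/2)² l at both scales; for cords this is a proxy (a cord is a
bundle, not a tube), which cancels in the ratio only to the extent that
cord porosity is width-independent.

**Robustness** removes measured edges in a scheme-defined order and
reports the fraction removed when the Root-connected fraction of
measured *length* (the natural biomass proxy) first reaches ≤ 0.5
(inclusive). Length, not edge count, defines "percentage of mycelium";
the removal count is normalized by edge count so the trait is
size-independent and admissible in cross-scale models (the raw count is
also retained). `random_chunk` removes a random edge plus its
chunk_k − 1 nearest remaining edges by midpoint distance, with
chunk_k = max(2, round(0.02 E)) by default — a 2% bite, chosen so chunk
attacks stay local but meaningfully larger than single bites; chunk
geometry is a modelling choice, recorded in output metadata. Stochastic
schemes default to 100 replicates and report the mean with per-replicate
values. Trajectories are computed by replaying removals backwards
through a union-find, so a full trajectory costs one pass.

## Ordination

Traits are standardized column-wise (n − 1 denominator), so total
inertia equals the trait count. The partial RDA
`traits ~ species + Condition(phylum)` is computed by QR projections:
Y and the species design are residualized on [1, phylum]; the
constrained inertia is the squared norm of the projection of the
residualized Y onto the residualized design; axes come from the SVD of
that projection. The partition total = conditional + constrained +
unconstrained holds to machine precision by construction, and the
implementation reproduces an independent constrained-ordination
reference (vegan) to ~1e-6 relative on a recorded 30×15 fixture —
eigenvalues, partition and pseudo-F alike.

pseudo-F = (constrained/df_model)/(unconstrained/df_residual), with
df from the ranks of the conditioned designs. Permutations shuffle rows
of the covariate-adjusted residuals (reduced-model permutation), the
exchangeable unit for a partial model; full-model permutation is
available as an option. p uses the add-one convention, so 9999
permutations bound p at 1e-4. Axis signs are fixed by making each
axis's largest-magnitude loading positive.

The full-trait models (micro-only, macro-only) use 15 traits with
global efficiency entering as G_eff/G_eff(MST) — the size-robust form
used for ordination displays. The cross-scale model keeps only the 10
size-independent or size-normalized network traits: meshedness,
G_eff-MST, Volume-MST, R_eff and RT_eff divided by hull area — the simplest size
normalization — and the five robustness fractions.

## Archetypes

Colonies are projected onto the first two principal components of the
standardized cross-scale traits. The minimal-area enclosing triangle is
found by flush-side search: the optimum has at least one side flush
with a hull edge and non-flush sides touching the hull at their
midpoints, so candidates are built from hull-edge flush lines plus
midpoint-rule third sides through each hull vertex, vectorized over all
candidates, and validated by exact hull containment (any candidate
smaller than the hull is rejected outright, which also eliminates
degenerate collapsed triangles). For k > 3 a greedy edge-flattening
heuristic is used and documented as such. The t-ratio is hull area over
triangle area; the null permutes every trait column independently
(marginals preserved, correlations destroyed), re-ordinates, and refits
— 10,000 randomizations by default, add-one p. k defaults to 3 with a
k-scan (3–5) helper, since k selection is ultimately a model choice.

## Synthetic colonies

The generator emulates the exploration phase of a colony growing from
a central inoculum into a uniform nutrient-poor arena. Tips advance in
discrete steps with persistent headings plus Gaussian noise
(log-normal step lengths, median `step_length_mu`), branch laterally
with per-step probability `branch_prob` at angle ~N(75°, 12°), and on
entering `fuse_radius` of an existing hypha either fuse (probability
`fuse_prob`, splitting the target edge at the capture point — an
anastomosis) or halt. Crossings always create nodes, so growth is
planar, like 2D extractions. Halting on contact also gives density
self-limitation, the one-parameter stand-in for space competition.
Widths are assigned after growth: log-normal with log-sd 0.1 (≈10% CV)
around `width_tip` for tip-incident edges and `width_main` otherwise —
log-normal rather than clipped Gaussian so hyphal dimensions follow the
near-log-normal distributions seen in real colonies, at numerically
indistinguishable moments. One seeded RNG stream per call; identical
parameters and seed give byte-identical edge lists.

Default arena radius is 350–450 µm with widths of 2–6 µm — a deliberately
desk-scale colony (hundreds of edges rather than the tens of thousands
of a full 10 mm plate), sized so that whole 60-colony studies, each
with robustness replicates, run in tens of seconds. The presets encode
the foraging gradient: guerrilla (branch 0.22, no fusion, 50 µm steps,
3.5/6 µm widths), phalanx (branch 0.5, fuse 0.65, 26 µm steps, 2/3.2 µm
widths), intermediate between. These choices follow the qualitative
ecology — phalanx phenotypes invest in many short thin cross-linked
hyphae, guerrilla in few long thick explorers — and they produce the
expected trait contrasts (meshedness, construction cost, global
efficiency and chunk robustness higher in phalanx; root efficiency
higher in guerrilla) as an outcome, not by construction of the traits.

What the generator does *not* emulate: nutrient fields and tropisms,
time-resolved growth, 3D structure, width tapering along a hypha,
curvature within an edge beyond heading noise, imaging artefacts other
than Gaussian blur and additive noise. Tests that pass on synthetic
colonies therefore validate the measurement chain and its invariances,
not biological realism of any particular species.

## Image extraction

Stages: top-hat background correction (structuring radius larger than
the widest hypha), optional multiscale Sato ridge enhancement,
thresholding, despeckling, topology-preserving skeletonization,
skeleton-to-graph conversion, distance-transform width estimation, spur
pruning. Extraction is deterministic.

Numerical choices worth recording:

- The default threshold is max(Otsu, median + 5·1.4826·MAD). Otsu alone
  always splits its input — on a structureless frame it binarizes
  noise, which percolates through despeckling; the robust background
  floor makes no-structure frames come out essentially empty.
- The ridge mode thresholds the Sato vesselness response: it is
  intensity-independent (useful under uneven illumination) but distorts
  widths, so the intensity mode is the default and the reference
  pipeline's exact enhancement operator remains a fidelity gap.
- Junction pixels (≥ 3 skeleton neighbours) are clustered within
  `node_merge_radius` (default 2 px) and collapsed to their centroid;
  thinning produces multi-pixel junction blobs.
- Arc length counts diagonal steps as √2 px and is floored at the
  endpoint chord, preserving the length ≥ chord invariant after
  centroid collapsing.
- Width = (2·median EDT − 1) px along the edge polyline; the −1
  corrects for samples sitting on pixel centres, and the median resists
  junction inflation. The along-edge summary is a choice; mean widths
  would be biased upward near junctions.
- Terminal edges shorter than 3 px-equivalents are pruned iteratively;
  the degree-2 chains this leaves are dissolved (lengths summed, widths
  length-weighted). Thinning erodes each hyphal end by about half its
  width, an irreducible ~1-pixel-scale bias on tip lengths.
- The inoculum is masked out as a user-supplied disk; nodes on its rim
  become the boundary set for Root attachment.

On noise-free rendered colonies the round trip recovers total length
within ~3% and length-weighted mean width within ~6% (worst of 20
seeds), with exact edge-count agreement on the tested colonies. Mean
width comparisons are length-weighted because plain per-edge means are
not invariant to how junctions subdivide hyphae.

## Known limitations

- Anastomoses and mere crossings are indistinguishable in 2D; both
  become junctions, as in any 2D extraction, overestimating true
  connectivity to the same degree.
- Convex-hull area overestimates the support of star-shaped sparse
  colonies, deflating their length density.
- The minimal enclosing polygon is exact (under the flush-side
  characterization) only for k = 3.
- Robustness models removal only; regrowth, septation and damage
  containment are out of scope.
- The permutation test assumes exchangeable colonies within species;
  time-series or spatially autocorrelated replicates would need
  restricted permutation schemes that are not implemented.
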