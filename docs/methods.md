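# Methods

## Problem and model

A catalytic site is modelled as an ordered list of 2–10 residues, each
with full heavy-atom coordinates, belonging to one chain of one structure
and labelled with an EC number, a SCOP superfamily and optionally GO term
sets per annotation domain (MF/BP/CC). Pose similarity between two sites
is defined over *matches*: injective, residue-type-compatible mappings
between the sites' residues. Each mapping is superposed optimally — a
proper rotation and translation minimizing the RMSD over the mapped,
represented points — and a site pair's comparison keeps every mapping
whose RMSD falls below a cutoff. The best match of an ordered pair
minimizes the chosen score (raw RMSD, RMSD_N1 = RMSD/(|ms|−1), or
RMSD_N2 = RMSD/max(1, 3|ms|−6)); ties break toward the larger match, then
the lexicographically smallest mapping, so results are deterministic.

Classification transfers the function of a query's best hit. In the
thresholded protocol, a hit scoring below cu_RMSD is a positive
prediction, judged correct (TP) if the functions agree — identical first
EC digit, or S_GO at or above cu_S_GO — and FP otherwise; hits at or
above the cutoff are FN/TN symmetrically. Sensitivity and the Matthews
correlation coefficient summarize the counts, and an exhaustive grid
search maximizes the MCC over the cutoff grid.

## Superposition and enumeration

Superposition uses the Kabsch algorithm (SVD of the 3×3 cross-covariance;
the reflection case is repaired by negating the smallest singular
direction, so only proper rotations are returned). Residuals are
evaluated explicitly rather than through the trace identity, which loses
precision catastrophically near RMSD 0; RMSDs below 1e−9 Å are reported
as exactly 0 (far below coordinate precision), which also keeps the
larger-match tie-break stable for exact copies.

Enumeration is a depth-first search over residue correspondences with two
exactness-preserving accelerations:

- *Distance pruning*: residue pairs (i,j) and (k,l) can only co-occur in
  a match of RMSD ≤ c over n points if their Cα distances satisfy
  |d_A(i,k) − d_B(j,l)| ≤ 2c√n (each point of a passing match deviates by
  at most c√n). A conservative upper bound on n is used.
- *Incremental Kabsch*: point sums, squared norms and the cross-covariance
  accumulate along the search path, so each candidate mapping costs one
  3×3 SVD; candidates near or under the cutoff are re-evaluated with the
  explicit residual.

A hard budget (10⁶ candidate mappings per site pair, configurable) turns
pathological pairs into a named error; the pipeline driver can optionally
treat such pairs as matchless.

Representations: Cα; Cα+Cβ (glycine contributes only Cα); Cα plus the
unweighted centroid of the side-chain heavy atoms; all heavy atoms
including the backbone (N, CA, C, O), in canonical PDB atom-name order —
hydrogens are always excluded. Points are paired by atom label on the
intersection of labels present in both residues, which also defines the
pairing for equivalence-paired residue types (Tyr/Phe and Ile/Leu or
Ile/Val presets; strict identity by default). Chemically
indistinguishable atom labelings (Asp OD1/OD2, Glu OE1/OE2, Arg NH1/NH2,
the Phe/Tyr ring flip) must not inflate the RMSD: both labelings are
tried per mapped residue and the lower RMSD kept. Up to six ambiguous
residues per mapping the labeling product is searched exhaustively (the
minimum is exact); beyond that, per-residue coordinate descent from the
default labeling. A Lipschitz bound — a relabeling perturbs the point
vector by at most the swap displacement norm, so it can lower the RMSD by
at most √(Σδ²/n) — skips the search when no labeling can reach the
cutoff.

## GO similarity

The term-set score S_GO must be normalized to [0, 1] and independent of
term frequencies in any corpus. Term–term similarity is the Wang
graph-based measure: a term's S-values over its ancestor DAG start at 1
and multiply by a relation weight per edge (0.8 for `is_a`, 0.6 for
`part_of`, maximum over paths); two terms score the summed S-values of
their common ancestors over their total semantic values, giving 1 only
for identical terms and 0 across namespaces. Term sets aggregate by the
symmetric best-match average within each namespace; the per-namespace
scores of the selected domains are averaged (namespaces lacking terms on
either side contribute nothing; if no selected namespace has terms on
both sides the pair's S_GO is undefined and the query is excluded from
confusion counting). Averaging per-namespace rather than pooling terms is
a deliberate choice: it keeps a namespace with many terms from dominating
the score.

## Evaluation protocol details

- Best hits are fixed before thresholding (they do not depend on the
  cutoffs); DIFF_SF mode removes same-superfamily candidates first.
- Queries without any admissible candidate are excluded from the counts
  (not counted FN) and reported as dropped.
- Best-of-k shortlists the k lowest-score candidates and returns the one
  with the highest S_GO (undefined S_GO ranks last; ties break toward the
  better score, then the smaller target id).
- MCC uses the zero-denominator convention (any zero factor → 0); this
  matters because a clean, all-positive query set has no negative class
  and an MCC of exactly 0 at every cutoff.
- Default grids: cu_RMSD 0.01–1.50 Å and cu_S_GO 0.50–1.00, both in steps
  of 0.01 — spanning every cutoff regime of interest at the precision the
  cutoffs are reported with. Grid ties break toward the smaller cu_RMSD,
  then the larger cu_S_GO (the stricter classifier).
- Reported values round half-up at two decimals.

## Synthetic data: what it emulates, and what not

Each function (family) has a template pose: residue types drawn from the
11 polar/charged amino acids with propensities dominated by His, Asp, Glu
and Ser — mirroring the observation that catalytic sites reuse a strictly
limited set of residue combinations, which is what makes cross-function
pose matches (the negative class) common — plus occasional hydrophobics
(rate 0.1); Cα positions sampled in a 6 Å sphere with pairwise distances
of 3–12 Å; side chains built from idealized internal coordinates
(standard bond lengths, tetrahedral/trigonal angles — no rotamer
libraries, which is sufficient for RMSD behaviour and needs no external
data). Site sizes follow a small-site-heavy distribution over 2–10
residues (mean ≈ 3.4, ≈30 % at the two-residue minimum). Family members
are rigid motions of the template plus i.i.d. Gaussian coordinate noise
(default σ = 0.3 Å, the order of crystallographic coordinate error) and
optional Tyr↔Phe / Ile↔Val substitutions (rate 0.05). Families cycle
through the six EC classes with distinct full EC numbers; by default 11 %
of functions are planted in two superfamilies (synthetic NISE). GO
annotations come from three binary `is_a` trees (CC with some `part_of`
edges): MF/BP leaves are shared by all enzymes of a function, CC terms
are drawn per enzyme independent of function — so including CC must
dilute a GO-based classification. All sampling derives from one seed;
fixed seed means identical output.

The generator does not emulate real backbones, ligands/cofactors/metals,
rotamer preferences, crystallographic artifacts, or the literature
curation process behind real site tables. Tests passing on this data
therefore validate the machinery (enumeration, superposition, scoring,
protocols) and the statistical behaviour under controlled noise — not
real-data performance, which depends on full structure databases.

One structural point discovered during design: with every family
multi-member and functions distinct, an unrestricted (ALL-mode)
evaluation has best hits that always share the query's function, the
negative class is empty, and the MCC is identically 0 by the
zero-denominator convention. The recovery and degradation experiments
therefore run in DIFF_SF mode with GO agreement — the planted NISE
functions supply the positives, single-superfamily functions the
negatives — which is also the mode of scientific interest
(non-homologs).

## Problem sizes and numerical choices

- Recovery experiment: 10 functions × 5 sites, σ = 0.1 Å, all-atom
  representation, enumeration cutoff 3.0 Å (large enough to populate the
  negative class with cross-function matches).
- Noise-degradation sweep: 6 functions × 3 sites, one third planted as
  NISE so both classes stay populated at this size; 20 seeds per noise
  level σ ∈ {0.1, 0.5, 1.0, 2.0} Å; medians compared.
- Superposition oracle cross-checks run on sites of ≤5 residues, where
  brute-force enumeration over all injective mappings is exact and cheap.
- PDB altloc ties break toward altloc 'A'; only the first model is read;
  EC numbers with fewer than four fields count as "no full EC number".

## Known limitations

- The curation cascade tests "multi-chain" on the site's residues, not
  the whole structure, and applies first-match precedence in the listed
  filter order; collections whose exclusion counts were tallied under a
  different precedence will disagree site-by-site (the totals conserve
  regardless).
- The exact literature formulas behind two further pose scores are not
  implemented; they are plug-in slots (`register_plugin`).
- Sequence-order information is ignored entirely (by design: catalytic
  residues are compared as unordered constellations).
- For sites with many repeated residue types the enumeration budget can
  trigger; the driver's skip option trades completeness for robustness
  and is reported per pair.
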