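# Methods

This note documents the models, numerical choices and limitations of
`mfskit`.  It is the package's own account of what is computed and why;
all quantitative statements below are recomputed by the test suite or
by `scripts/acceptance.py`.

## Coordinate model

Structures are read through gemmi (PDB and mmCIF) into a flat
residue/atom model.  Only the first model of multi-model (NMR) files is
kept, with a warning.  Alternate locations collapse to the
highest-occupancy conformer, ties broken by altloc letter, giving a
deterministic single-conformer model.  Hydrogens are parsed and flagged
but excluded from every distance rule (donor detection, site merging,
environment search).  Crystal symmetry mates are **not** generated:
a ligand contributed by a symmetry-related chain will be missed.  This
is a known caveat of working with deposited asymmetric units.

Metal classification uses an explicit periodic-table set (alkali,
alkaline-earth, transition, post-transition metals, lanthanides,
actinides — including Na, K, Mg, Ca).  Metalloids (B, Si, As, Se, Te,
Ge, Sb) are excluded by default; both directions are configurable
(`Config.extra_metals` / `excluded_metals`) because the inclusion of
borderline elements is a policy choice, not a fact of chemistry.

## Site extraction

**Donor detection.**  Crystal structures carry no explicit coordination
bonds, so donors are detected geometrically: a non-hydrogen atom of a
donor element (N, O, S, Cl, Br, I, Se, P, F by default) is a donor if
its distance to the metal is at most r_cov(metal) + r_cov(donor) +
0.5 Å, capped at 3.0 Å.  Covalent radii come from gemmi's element
table.  The 0.5 Å pad absorbs coordinate error in real structures; the
3.0 Å cap prevents large radii (e.g. alkali metals with iodide) from
producing chemically absurd cutoffs.  Donors are tagged endogenous
(polypeptide/polynucleotide residues) or exogenous (water, anions,
organic cofactors) by the kind of their owning residue.

**Polynuclear merging.**  Metal ions sharing at least one ligand
residue, or separated by strictly less than 5.0 Å, belong to one site;
the relation is closed transitively (connected components, via
networkx).  The boundary is strict: ions at exactly 5.000 Å are not
merged.  The independent test oracle recomputes the same components
with a hand-written union-find over brute-force distances.

**Environment.**  The MFS adds every residue (of any kind, waters
included) with at least one non-hydrogen atom strictly within 5.0 Å of
any non-hydrogen atom of any ligand residue — all atoms of the ligand
residues count, not only the donor atoms, because the rule is stated on
"the ligand itself".  Metal-bearing hetero residues of the site and the
ligands themselves are not environment.

**Fragments and MBP.**  MFS polymer residues split into maximal runs of
sequence-consecutive residues per chain (author numbering; insertion
codes stay within a run).  The metal-binding pattern lists the
one-letter codes of the amino-acid ligands in chain/sequence order with
`X(n)` spacers counting intervening sequence positions; chain breaks
are marked `/`.  Nonstandard residues map to their tabulated parent
(MSE → M), else `X`.

**Adventitious-site filter.**  For statistics only (never at
extraction), sites are dropped unless every metal ion has at least the
per-element minimum donor count: Zn 3, Fe 4, Ca 4, Cu 2, all others 1.

## Superposition

**Pose enumeration.**  Each site is decomposed into triangle units:
the geometric center of its metals (the "virtual atom" for polynuclear
sites) plus an unordered pair of donor atoms — C(d, 2) units for d
donors.  Every query unit is overlapped with every target unit in both
donor pairings by a proper rotation (SVD alignment of the unit
direction vectors and their cross product) with the metal centers
pinned coincident.  Two numerical safeguards, added as this package's
own design decisions:

* when a unit's two donor directions are within ~45° of collinear or
  antipodal (|cross| < 0.7), the spin about the common axis is poorly
  conditioned, so 12 spin-sampled variants of the base rotation are
  appended (extra candidates only — exactness is preserved);
* a site with a single donor falls back to one axis-aligned unit with
  12 spin samples, with a warning.

Near-duplicate rotations (max matrix deviation < 1e-6) are removed.

**Matching.**  Greedy one-to-one nearest-neighbour assignment of Cα
atoms (C1′ for nucleotides) by ascending distance, ties broken by atom
order for determinism.  Thresholds: 2.0 Å, relaxed to 5.0 Å for
metal-binding residues, which can only match metal-binding residues.
Cβ (N9/N1 base atoms) pair only inside an existing Cα (C1′) pair and
under the same threshold.  The greedy ascending-distance rule is our
resolution of a per-query "closest atom" description that could
otherwise assign one target atom twice.

**Score.**  `T = w1·(Σ_f 1/n_f)/N + w2·ln(C_max/c) + w3·max(0, 1 −
S/S_max)`, lower is better.  Alignment fragments are maximal runs of
matched residue pairs consecutive in *both* chains.  `C_max` counts the
Cα+Cβ atoms of the smaller site, `c` the matched atom pairs (atoms, not
residues).  `S` sums BLOSUM62 over matched residue pairs; `S_max` sums,
per pair, the larger of the two self-substitution scores, which
guarantees S ≤ S_max; the term is clamped at 0.  Nucleotide pairs use
identity scoring (match 1 = self-score, mismatch 0).  An empty
correspondence gets an infinite sentinel score.

**Refinement.**  The top 10 poses by score are refined: a Kabsch
least-squares fit over the matched Cα/Cβ pairs *plus the metal-center
pair*, iterated with re-matching until the correspondence is stable (at
most 8 rounds) — a single pass can leave most of a site unmatched when
the initial pose comes from a short-lever donor triangle.  The reported
RMSD runs over the matched pairs plus the metal-center pair (the metal
pair counts in both the sum and the denominator).  Degenerate
(collinear) point sets fall back to the unrefined pose with a warning.
After refinement all candidates are re-scored and re-ranked; ties break
by lower RMSD, then enumeration order.  Metals may drift slightly off
coincidence after refinement; enumerated poses keep them coincident to
1e-9 Å.

**Weights.**  The three weights are free parameters of the method; the
defaults (2.75, 2.75, 2.75) are set by `scripts/calibrate_weights.py`,
which maximizes the minimum of the two margins
(2.25 − q95(near-duplicate scores)) and (q05(unrelated scores) − 3.0)
over a grid of weight directions and scales, on 40-pair panels
(near-duplicates: 0.3 Å RMS displacement + 10% mutations; unrelated:
random sites differing in geometry or ligand composition).  Uniform
weights won; only the overall scale is really constrained by the
threshold semantics.  With these defaults, 97–98% of near-duplicate
pairs score ≤ 2.25 and 95–100% of unrelated pairs ≥ 3.0 (seed
dependent; recomputed by the acceptance script).

**Asymmetry.**  The score is mildly directional (matching runs from the
query side).  Wherever a symmetric dissimilarity is needed (clustering)
the mean of the two directed scores is used.

## Search

A site library stores one PDB block per MFS plus a JSON index; loading
re-extracts each site from its block, which is lossless because an MFS
excerpt re-extracts to itself.  Search scores every entry (no
metal-identity prefilter unless the user asks for one — structural
similarity is metal-agnostic), sorts ascending, breaks ties by entry
id, and applies the score threshold.  Per-entry scoring is independent,
so results do not depend on evaluation order.

## Clustering

**Equistructural grouping.**  Pairs of sites qualify when their source
chains share ≥ 50% global sequence identity (Biopython global alignment,
BLOSUM62, gap open −10 / extend −0.5; identity = identical pairs /
alignment columns) — or a user-supplied fold label, standing in for
external domain databases — *and* their site centers lie < 3.5 Å apart
after a least-squares Cα fit guided by that alignment.  Groups are the
transitive closure.  Chains under 10 residues yield singletons with a
warning.  Equivalent-site subsets additionally share the metal element
multiset and nuclearity.

**Two stages.**  Within each group: complete-linkage hierarchical
clustering (scipy) cut at 2.25, which guarantees every intra cluster's
maximum internal score ≤ 2.25; the representative minimizes the sum of
scores to its cluster mates (ties by site id).  Across representatives:
average-linkage cut at 2.75, free to merge sites from different folds.
Infinite scores are capped at 1000 to keep the linkage arithmetic
finite.  Test oracles: exhaustive partition enumeration (4 items) and a
hand-computed 3-item average-linkage case.

## Synthetic structures

The generator builds sites with exact, controllable geometry: the metal
at the origin, donors on ideal tetrahedral/octahedral/linear (or
custom, possibly jittered) vertices at the requested distance, each
ligand's Cβ/Cα placed radially behind its donor, filler residues
threaded along spherical arcs between ligand anchors (long sequence
gaps bulge outward), and optional distant tail residues (> 12 Å) to
give chains a non-site context.  Families derive from a base site by
point mutations of non-ligand (optionally non-MFS) residues, isotropic
per-atom Gaussian noise and a random proper rigid motion, with family
labels recorded as ground truth.  `noise_sd` is the per-coordinate
Gaussian sd; panels quoting "0.3 Å noise" use sd = 0.3/√3 so the RMS
atomic displacement is 0.3 Å.  Identical spec + seed reproduces output
byte for byte.

What the generator does **not** emulate: real backbone torsions
(no Ramachandran enforcement), side-chain rotamers, sterics, crystal
contacts, solvent networks, or correlated (domain-level) motions.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under controlled geometry, not parser- or
chemistry-level robustness against the full heterogeneity of the PDB.
The random-panel conditions are: random metal among 8 common elements,
2–6 donors, jittered randomly oriented coordination frames, random
filler sequences, metal–donor distance = covalent-radius sum −
U(0.05, 0.25) Å, 1–3 fragments.  "Unrelated" pairs are constrained to
differ in coordination geometry or ligand composition; without that
constraint two small random sites can be genuinely similar and score
accordingly.

## Statistics

Nuclearity/fragment statistics count only fragments containing at least
one amino-acid ligand, over sites passing the minimum-donor filter;
heterometallic sites pool under "mixed".  Sub-pattern alignment anchors
fragments on ligand residues matching the sub-pattern spacing (e.g.
`HX(2)C`); positional enrichment is observed/background frequency per
relative position, with an error on zero background for an observed
residue.  Background frequencies must be supplied for biological
claims; the uniform default exists for testing.  The MFS-vs-chain
identity comparison uses, per cluster, the mean pairwise identity over
matched residue pairs of the structure-based MFS alignment
(symmetrized) against the mean global chain identity over the same
pairs; the paired-difference summary reports both a paired t-test and a
sign-flip permutation test (default significance level 0.01), since
normality of the per-cluster differences is not guaranteed.

## Problem sizes

Default panels: 100–200 random fixtures for the extraction oracles,
100–200 superposition trials per threshold band, 10–20 two-family
replicates (3 members each) for cluster separation, 1000 fragments for
the enrichment null, 1000 random transforms for refinement optimality.
These sizes give binomial error bars of a few percent on the reported
rates while keeping a full run in the low minutes on one core.

## Known limitations

* No symmetry expansion; sites completed by crystal symmetry are
  truncated.
* No electron-density validation of metal identity; deposited element
  assignments are taken at face value.
* Exogenous cofactor atoms (e.g. heme ring atoms) contribute donors for
  pose enumeration but have no Cα/Cβ, so they do not enter the
  correspondence or the score.
* The ≥ 50% identity route is the only built-in equistructural
  criterion; fold labels must be supplied externally if homology is
  lower.
* Scores are calibrated on synthetic panels; on real PDB sites the
  published interpretation bands should be treated as indicative until
  validated against reference superpositions.
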