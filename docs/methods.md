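# Methods

This note records the models, conventions and numerical choices behind
`pepagg`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: enough detail to reproduce or challenge any
number the code emits.

## System and units

The reference system is 27 capped octapeptides (NFGAILSS or an
alanine-scan variant) in a cubic periodic box of edge 104 Å, i.e.
~40 mM peptide (`solute_concentration(27, 104) = 39.86 mM`), with frames
every 10 ps. Coordinates are ångström throughout, times picoseconds,
energies kcal/mol. Frames are 0-indexed internally; reported times are
ps. All distances are minimum-image in the cubic box; the neighbour
search uses a periodic k-d tree (`scipy.spatial.cKDTree` with
`boxsize`), which is exactly equivalent to the all-pairs minimum-image
search (asserted against a brute-force oracle in the tests).

Peptides carry an N-terminal acetyl (ACE) and C-terminal N-methylamide
(NME) cap. Caps participate in cluster contact detection (the contact
criterion reads "any two atoms") but are excluded from the
Kabsch–Sander residue set, from per-residue H-bond statistics and from
side-chain contact statistics.

Van der Waals radii default to the Bondi table by element (H 1.20,
C 1.70, N 1.55, O 1.52, S 1.80 Å); the table is selectable by name so
other conventions can be added.

## Clustering and mean cluster size

Peptides i and j are in contact when some atom pair (a∈i, b∈j) has
minimum-image distance strictly below r_vdw(a)+r_vdw(b); ties at
exactly the radius sum are non-contacts. Clusters are connected
components of the contact graph (scipy.sparse.csgraph); isolated
peptides are singletons with CS = 1. MCS is the per-peptide mean of CS,
so a frame's MCS equals Σ size²/N — each cluster weighted by its own
size. Window averages (e.g. "last 30 ns" analyses) are unweighted means
of per-frame MCS over frames whose times fall in the closed window.

## Kabsch–Sander secondary structure

The assignment is implemented, not delegated: H-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5, candidate pairs prefiltered at Cα–Cα < 9 Å, energies clamped
at −9.9. Amide H positions use the explicit atom when present and the
standard DSSP reconstruction H = N + unit(C_prev − O_prev) otherwise
(this is the convention of the dssp-2 code and its ports, and is what
the reference implementation used in the tests applies; a bisector
placement differs by fractions of a degree on ideal geometry but can
flip marginal bonds).

Pattern rules: n-turns (i+n → i bonds, n = 3, 4, 5) are intra-peptide;
two consecutive n-turn starts give G/H/I over n residues. Bridges
follow the canonical definitions — parallel when
(Hb(i−1, j) ∧ Hb(j, i+1)) ∨ (Hb(j−1, i) ∧ Hb(i, j+1)), antiparallel
when (Hb(i, j) ∧ Hb(j, i)) ∨ (Hb(i−1, j+1) ∧ Hb(j−1, i+1)), where
Hb(a, b) means the C=O of a accepts from the N-H of b — for residues in
different peptides or ≥ 3 apart within one peptide. Inter-peptide
bridges are essential here: β structure in these systems forms by
association. Consecutive bridges form ladders; an isolated bridge is B,
ladders are E (β-bulge merging is not implemented; the idealised
fixtures contain none, and bulges in noisy data would at worst relabel
an E as B). Priority when patterns overlap follows Kabsch–Sander
ordering as implemented in dssp-2: strand/bridge first, α-helix (H)
overrides, then G and I only into remaining coil, then turns (T), then
bends (S, κ > 70°), else C. Only H/G/E/B are contractually compared to
the reference implementation; T/S/C boundaries differ between DSSP
variants and are tolerated.

β% = 100·(#E+#B)/#residue-frames and helix% = 100·(#G+#H+#I)/#residue-frames
over sequence (non-cap) residues. Bridge-topology percentages count
residue-frames participating in at least one bridge of each class, on
the same denominator.

## Interaction statistics

Hydrogen bonds use the HBPLUS default geometry (D–A < 3.9 Å,
H–A < 2.5 Å, D-H-A angle > 90°), configurable; bonds are inter-peptide
only and classed MM/MS/SS by the main-chain flag of donor and acceptor
heavy atoms. Backbone donors without an explicit H get the DSSP
reconstruction; side-chain donors require an explicit H (synthetic
topologies are heavy-atom + amide-H, so side-chain donors are inactive
there — acceptors still yield MS bonds). "Per residue" divides by the
number of sequence residues in the system (27 × 8 = 216 at study
conditions); Total = MM + MS + SS exactly, before display rounding.

Side-chain contacts: "aliphatic carbon" means sp³ side-chain carbons
(CB and beyond); Phe ring carbons (CG…CZ) are excluded from the
aliphatic set and feed the ring-centroid stacking criterion instead, so
the two criteria are disjoint; Asn's sp² CG is likewise excluded. A
residue pair counts at most once per frame however many atom pairs are
within 5.5 Å, preventing large side chains from dominating by atom
count. Pair labels use one-letter codes with Ser kept position-resolved
(S7 vs S8). Because "total per residue" can count each contact once or
once per participating residue (the conventions differ by ×2), the
table exposes both (`total_per_residue`,
`total_per_residue_participating`).

Phe stacking: ring centroid = mean of the six ring carbons after
unwrapping the ring across the periodic boundary; a stacked pair is two
inter-peptide rings with centroids < 5 Å.

## Markov state models

States are assigned per entity per frame: cluster-size states 1…N per
peptide; six residue states crossing {coil, strand = E/B,
helix = G/H/I} with the parent peptide's oligomeric status (cluster
size ≥ 2). Transitions are pooled over entities at a lag of one saved
frame (10 ps; configurable) into the count matrix T; N_i is defined as
the row sum Σ_j T(i, j) — defining N_i as raw state occurrences instead
would count final-frame occupations that have no outgoing transition
and break row-stochasticity, which the propagation π(n) = π(0)·Pⁿ
requires. Unvisited states receive identity rows so Pⁿ is well defined;
they are flagged in the results. π(0) defaults to the empirical
occupancy of the first frame. No reversibility constraint, no
implied-timescale analysis: raw counts only, propagated by repeated
vector-matrix multiplication. Headline quantities are the maximum over
propagation steps of the summed occupancy of a state subset (e.g.
oligomeric helix), and per-n-mer occupancy curves with a display-only
5% threshold.

## Synthetic generator

The generator emulates what the analysis needs from aggregation MD —
peptides that diffuse, meet, and coalesce into clusters that then move
as units — not the physics that produces it:

* **Start**: extended capped peptides (φ = −139°, ψ = 135°, fixed
  representative rotamers) on a 25 Å cubic grid centred in the box, all
  parallel. An extended octapeptide is ~30 Å long — longer than the
  grid spacing — so the common long axis points along the box diagonal,
  giving ≥ ~15 Å clearance between grid neighbours; every peptide is a
  monomer at t = 0 by a wide margin.
* **Dynamics**: per frame, each cluster takes a Gaussian translational
  step (σ = 2.5 Å per axis), a small rigid rotation (σ = 10°), and a
  1 Å drift toward the nearest other cluster. The drift plays the role
  of the effective attraction that makes aggregation-prone peptides
  coalesce; with it, 27 peptides reliably reach a single 27-mer within
  a few hundred frames, which pure random walks in a 104 Å box do not
  do on that timescale.
* **Sticking**: a move that brings a cluster into atom-level vdW
  contact with others merges them with probability `stick`; otherwise
  the move is rejected (all-or-nothing over the touching set), so in
  every emitted frame contact ⇔ same bookkeeping cluster — the
  clustering module must and does reproduce the generator's own labels
  exactly. Merged clusters are first translated by whole box vectors to
  be Euclidean-contiguous (a cluster absorbed through the periodic
  boundary would otherwise change minimum-image geometry under
  rotation). With probability `unstick` a cluster sheds a random
  member to a random contact-free position; the remainder is re-split
  into contact-connected components, since the leaver may have been the
  bridge.
* **Limitations**: peptide internal geometry is frozen (rigid bodies) —
  secondary-structure *dynamics* are exercised separately by the ideal
  helix/sheet fixtures; there is no excluded volume, no solvent, no
  force field. An optional `helix_fraction` freezes a fraction of
  peptides in helical conformation so the residue-level MSM has
  non-trivial structure states; the default (0, all extended) matches
  the study's starting conditions. Passing tests on this generator
  demonstrates correctness of the analysis operations, not fidelity of
  any biophysical observable: β content from randomly docked rigid
  extended peptides is near zero, and H-bond counts are far below those
  of relaxed MD ensembles.
* **Fixtures**: ideal helices are built at φ = −57°, ψ = −47°; sheets
  place a second strand by a frozen rigid transform (offset −2.25 Å
  along the strand axis at 4.5 Å spacing, 180°-flipped, for
  antiparallel at φ = −139°, ψ = 135°; offset −1.75 Å, unflipped, for
  parallel at φ = −119°, ψ = 113°) chosen so the Kabsch–Sander bridge
  registry is exact; both are verified against a reference DSSP
  implementation in the tests. Markov-chain ensembles start uniformly
  over states and follow a user-supplied row-stochastic matrix.

All generators draw from a single `numpy.random.default_rng(seed)`
stream in a fixed order and are bit-reproducible.

## Pipeline and reporting

`run_pipeline` is a pure function of (inputs, config, seed): stages are
clustering → secondary structure → interactions → MSMs → writers, any
stage failure aborts with the stage name, and reruns with the same
config are byte-identical. The default analysis window is the last 30%
of the trajectory (the analogue of last-30-ns-of-100-ns analyses),
overridable by explicit bounds. Display rounding (2 decimals for the
H-bond table, 1-decimal percents for the contact table, whole percents
for the MSM table) happens only in the CSV writers; the JSON manifest
keeps full precision. Configuration is schema-validated with unknown
keys rejected, so typos fail loudly.

`scripts/acceptance.py` re-derives the headline numbers at run time:
problem sizes are 200 random graphs (≤ 27 nodes) for the clustering
oracle, 50 × 2000-step chains (10⁵ pooled transitions) for MSM
recovery, 44 residues across three ideal fixtures for the DSSP
comparison, and a 27-peptide × 500-frame aggregation run (analysed
twice) for the end-to-end and determinism checks — sizes at which every
check is exact or statistically comfortable while the whole script
completes in well under a minute on one CPU.

## Known limitations

* The PDB reader handles the residue chemistry of this study (the seven
  residue types plus caps), not arbitrary proteins; unknown residues or
  atoms are hard errors by design.
* β-bulge merging and chain-break detection inside a peptide are not
  implemented (synthetic inputs cannot produce either); π-helix
  assignment follows dssp-2 priority, not the π-preferring variant of
  dssp-4.
* Either capping order (including N-methyl at the N-terminus, which
  some studies report) is accepted on input, but the builder emits the
  standard ACE/NME arrangement.
* MSMs are estimated at a single lag with no uncertainty quantification
  beyond the recovery test; occupancy maxima are point estimates.
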