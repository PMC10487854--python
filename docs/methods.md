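# Methods

This note documents the models, conventions and numerical choices behind
`g4kit`, and what the synthetic generators do and do not emulate.

## Scope and system

The package analyses tetramolecular parallel G-quadruplexes of the kind
formed by the ALS/FTLD-associated d(G4C2) hexanucleotide repeat: four
strands related by a C4 axis, a stack of four G-quartets with a syn
5'-terminal quartet, a C-quartet on the 3' side, monovalent cations
(K+ or 15NH4+) in the inter-quartet channel sites (named O5, I, O3 from
the 5' end, plus the G4/C5 cavity OGC and, in 5'-5' stacked dimers, the
interface site OGG), NMR magnetization-exchange kinetics of those
cations, and stage-wise free-energy reconstruction of cation passage
along the channel.

## Structure handling

Coordinates are multi-model PDB ensembles (gemmi does the parsing and
writing). Every model must list the same atoms in the same order;
alternate locations other than blank/A are dropped; residue numbering is
taken from the file. Ions are single-atom HETATM residues recognised by
residue name (`K`, `NH4`, `NA`, ... — configurable); for ammonium the
nitrogen is the positional atom.

## Quartet detection

Hydrogen bonds are searched only over the quartet-defining
donor/acceptor identities: guanine Hoogsteen N1H...O6 and N2H...N7, and
cytosine amino N4H...O2. A candidate qualifies when the heavy-atom
donor-acceptor distance is <= 3.5 Å; when the donor hydrogen is present
in the file the best D-H...A angle must also be >= 120°. Deposited NMR
models sometimes lack hydrogens, in which case the distance criterion
alone applies — a deliberate fallback, not a relaxation of the default
behaviour.

A directed graph connects each residue to the residue its primary donor
bond (N1H...O6 or N4H...O2) reaches; every simple directed 4-cycle of
same-type bases that is coplanar (maximum base-atom deviation from the
SVD-fitted plane < 1.0 Å by default) is a quartet. Cycles are
canonicalised to start at the lowest chain id and follow the
donor→acceptor direction. Quartets are sorted along the channel axis
(best-fit line through quartet centers) oriented 5'→3' along the first
chain, and their normals are flipped onto that direction.

**Center convention.** The quartet center is the centroid of the four
carbonyl oxygens lining the channel (O6 for G, O2 for C) — these are the
negative charge centers that build the cation coordination cage, which
is what the inter-quartet alignment parameter is about. An
all-heavy-atom centroid is available by flag.

## Step geometry

For two stacked quartets with centers c1, c2 and 5'-side plane normal
n1:

* rise = |(c2 − c1) · n1|,
* d = |(c2 − c1) − ((c2 − c1)·n1) n1| — the in-plane offset between the
  first center and the projection of the second center onto the first
  quartet's plane. By construction d² + rise² = |c2 − c1|² identically.
* twist = circular mean over the four strands of the signed angle
  between the center→C1' directions of corresponding residues, projected
  onto the mean plane; positive twist is a right-handed rotation
  advancing 5'→3'.

Strand correspondence is by chain id within one core; across a stacking
interface (no shared chains) residues are paired by nearest projected
base centroid via optimal assignment, i.e. by which base actually stacks
on which.

**Stacking modes.** The five- and six-membered ring polygons of each
stacked residue pair are projected onto the mean plane and clipped
(shapely). The step is labelled by the ring pair with the largest mean
overlap (`five_six` pools 5-on-6 with 6-on-5); `partial_six` is the case
where only the six-ring overlap survives the threshold (default 5% of a
six-ring area) but covers less than half a ring; `none` when all
overlaps are below threshold. The half-ring bound separating `six_six`
from `partial_six` is a design choice — the literature describes these
modes qualitatively.

**Polarity.** The donor→acceptor cycle's circulation vector is compared
against the viewing direction (default: the 5'→3' normal, i.e. the view
from the 5' side). The cycle is anticlockwise when the circulation
points at the viewer. The label flips under reflection in a plane
containing the view axis and under view reversal — both are exact
symmetries and are tested as such.

**Glycosidic torsion.** chi is O4'-C1'-N9-C4 (purines) or O4'-C1'-N1-C2
(pyrimidines), reported in [0°, 360°). Classification: syn when the
(−180°, 180°]-wrapped value lies in (−90°, 90°], anti otherwise. This is
deliberately a superset of the 30–90° / 200–280° windows used as
refinement restraints, so conformers slightly outside restraint bounds
still classify.

**Grooves.** The width of the groove between two cyclically adjacent
strands is the mean closest P–P distance between them over the quartet
residues; classes are narrow < 14 Å <= medium <= 19 Å < wide
(configurable).

**Ion assignment.** Ions are projected onto the channel axis; an ion
within 3.0 Å radially (configurable) whose axial coordinate falls in an
inter-quartet interval gets that interval's site name (O5/I/O3/OGC/OGG,
primed for a second core), otherwise bulk. All pairwise ion–ion
distances are reported alongside.

## Ensemble RMSD

Superposition is least-squares with proper rotations only (Kabsch, via
scipy's `align_vectors`). The headline statistic is the mean RMSD over
all C(M,2) model pairs of the heavy atoms in a selection, each pair
superposed independently; the RMSD-to-mean-structure reading is computed
alongside because published "pairwise RMSD" values are sometimes one and
sometimes the other. Default core selection: all heavy atoms of the
G-tract residues.

## Exchange kinetics

Autocorrelation peak volumes versus mixing time are fit with the
bi-exponential

    V(tau) = A1 exp(−r1 tau) + A2 exp(−tau/T1),   A1, A2 >= 0; r1, T1 > 0,

and cross-peaks with the build-up

    V(tau) = A exp(−tau/T1) (1 − exp(−k tau)),    A, k >= 0, T1 fixed,

using bounded nonlinear least squares (lmfit, cost tolerance 1e-10, at
most 1e4 evaluations) with deterministic multi-start initialisation
(log-linear fits of the early/late decay thirds plus perturbed splits;
best of n wins, and the best-of-n residual is non-increasing in n).
Volumes are unweighted by default. The two bi-exponential terms are
mathematically exchangeable, so fits are canonicalised amplitude-major
(A1 >= A2); the fit is flagged unidentifiable when the two rates agree
within 10% or an amplitude vanishes. The T1 handed to the cross-peak
fits is the slow decay time constant of the appropriate autocorrelation
peak — the bulk peak B for pathways to/from solution, the inner-site
peak I for movement within the quadruplex — mirroring the experimental
procedure. Volumes are normalised so the O5 autocorrelation peak is 100
at the shortest mixing time (13 ms).

**What the apparent rate means.** For a one-way two-site exchange with
equal T1, the cross-peak is exactly the build-up equation and k is the
microscopic rate. In a multi-site network the fitted k tracks the origin
site's *total* escape rate (plus backflow distortion), so pathway rates
are recovered quantitatively only when the fitted pathway dominates its
origin's outflow — the regime the recovery tests use. The package
reports these as *apparent* rate constants, which is also what the
experiment yields.

**Synthetic network.** The simulator propagates M(tau) =
expm[(K − R) tau] M(0), with K the master-equation generator
(K[dst,src] = rate, diagonal = −outflow; column sums vanish, so
magnetization is conserved when relaxation is off) and R = diag(1/T1).
Autocorrelation volumes are the diagonal transfer amplitudes times the
initial magnetization; cross-peaks the off-diagonal ones. Optional
multiplicative Gaussian noise (seeded) emulates integration error. The
default network has sites B, O5, I, O3 with microscopic rates O5→I 0.3,
I→O5 0.5, I→O3 0.4, O3→I 0.9, O3→B 0.9 s⁻¹ and no B→O3 return, initial
magnetization 2:1:1 for O5:I:O3 over a large bulk pool, and T1 of
0.45–0.6 s. These were chosen once so that the *fitted apparent* rates
reproduce the qualitative experimental picture — fastest movement out of
the 3'-outer site near the ~2 s⁻¹ ceiling, slower interior hops, an
exit-only 3' end and a closed syn 5' end; the T1 values are typical of
bound/bulk ammonium and are not printed quantities. The mixing-time grid
is 16 points geometric from 13 ms to 3 s.

## Jarzynski PMF

The stage free energy is dF = −kBT ln[(1/N) Σ exp(−Wi/kBT)] with
kB = 0.0019872 kcal mol⁻¹ K⁻¹, evaluated by log-sum-exp (no overflow
for works spanning ±500 kcal/mol). Contiguous stages (default: 14 stages
of 1 Å, 100 trajectories each, 300 K — the adaptive steered-MD layout
for this system) are stitched cumulatively, anchored at zero. The
adaptive handoff selects the trajectory whose terminal work is closest
to the stage dF, ties to the lowest index. Barrier heights are
max-minus-window-start over a position window. Jensen's inequality
(dF <= mean work, strict for non-constant works) holds by construction
and is property-tested.

## Synthetic coordinate builder

Four symmetry copies of an idealized planar base template (standard
nucleobase geometry) are placed per quartet. The template's in-plane
pose is calibrated once per base type by pinning the channel-lining
carbonyl oxygen on a fixed ring radius (2.45 Å for O6, 2.55 Å for O2)
and solving the rotation about it so the donor–acceptor distances to the
+90° copy take the canonical ~2.86 Å value; of the two roots the one
whose amino hydrogens point at the acceptor is kept. Quartets are
stacked with exactly the requested per-step rise/twist/in-plane offset,
so every geometric parameter is recovered by the geometry module to
1e-6. The glycosidic class is realised by placing O4' at chi = 60°
(syn) or 240° (anti) by internal-coordinate construction; a backbone
phosphorus marker is placed radially outward so groove widths land in
the medium class typical of all-parallel quadruplexes. Ions go at
inter-quartet midpoints. A two-core spec stacks a mirrored copy 5'-to-5'
at the requested interface rise/twist (defaults 3.57 Å, 14.8°); the
measured interface stacking mode at the defaults is five_five, as
expected for that geometry.

**What the builder does not emulate.** The base layer is identical for
syn and anti quartets (only the sugar moves), so the polarity reversal
that an all-syn quartet shows in real structures is not reproduced;
polarity is verified through its exact mirror/viewing symmetries
instead. The backbone is schematic (C1', O4', P only), there are no
loops or solvent, and quartets are perfectly planar. Passing round-trip
tests therefore demonstrates correctness of the descriptors'
definitions, not robustness to the full irregularity of experimental
coordinates; the planarity and H-bond cutoffs (1.0 Å, 3.5 Å/120°) are
set wide enough for deposited NMR ensembles.

Synthetic NMR-style ensembles for the RMSD machinery apply seeded
per-atom Gaussian scatter, larger on the C-quartet than on the G-core,
emulating the convergence pattern of refined ensembles (tight core,
looser periphery); mean pairwise RMSD of such an ensemble is √6·σ for
scatter σ, which the tests verify.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical spec + seed gives bit-identical
output. Test and analysis problem sizes — a single-model builder
structure (~330 atoms), 10-model ensembles, 16-point mixing-time grids,
100 noisy replicates, 14×100 work samples, 1e5-sample Gaussian checks —
were chosen as the smallest sizes at which the statistical assertions
(3-standard-error closed-form checks, 30%-in-90%-of-replicates recovery)
are stable across seeds.

## Known limitations

* Quartet detection assumes the canonical pairing chemistry; mixed
  G:C quartets, triads and i-motifs are out of scope.
* The exchange model is first-order and ignores scalar/dipolar
  cross-relaxation pathways; the apparent-rate caveat above applies.
* Free energies from stage-wise Jarzynski are upper-biased at small
  trajectory counts (the exponential average is dominated by rare low
  work values); the package reports the plain estimator without
  bias correction.
* The printed free-energy barriers, exchange rates, occupancy ratios,
  diffusion coefficients and melting temperatures of the real system
  derive from full MD simulations and NMR experiments; they are not
  recomputable from coordinates alone and are covered here by the
  property-based suites, not numeric reproduction.
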