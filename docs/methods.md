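# Methods

## Representation

The system is coarse-grained at two resolutions simultaneously. Structured
regions (tubulin monomers, the NDC and CDC domains) carry one bead per residue
at the Cα position *and* scoring beads of up to 10 consecutive residues;
disordered regions (linker, C-tail) carry only the ≤10-residue scoring beads.
Each structured segment is a rigid body: all of its beads move together, so
intra-body distances are exact invariants of the sampling. Crosslink distances
are measured between per-residue beads where the region is structured and
between containing scoring beads otherwise; excluded volume and connectivity
act on the scoring resolution only. For the real DCX construct the modeled
ranges are NDC 51–140, CDC 174–251 (globular) or 174–253 (open), with the
1–50 and 331–360 tails excluded.

A bead covering residues r₁..rₙ gets the radius of the sphere whose volume
equals the summed per-residue volumes (a bundled 20-entry mean-residue-volume
table, Å³) and the summed average residue masses. Disordered beads are
initialized on a straight path between their structured anchors with ≤1 Å
jitter; their positions are randomized away by sampling anyway.

The MT wall is a planar patch: an α/β dimer replicated by a lateral and a
longitudinal rigid transform on an n_pf × n_dimers grid. Only local junction
geometry matters for domain docking, so helical lattice parameters are not
modeled; transforms can be fitted from a multi-chain structure by neighbor
superposition (Kabsch) or supplied directly. Interior junctions are the grid
vertices flanked by four complete dimers; edge vertices are retained so the
edge filter can assign any model to its nearest vertex (ties break toward
interior, i.e. toward keeping the model).

## Restraints

* **Crosslinks** use a two-state mixture score per link,
  −log[(1−ψ)P + ψ(1−P)] with P = 1 − Π(1 − p(d)) over all admissible
  site/copy assignments and p(d) = 1/(1+exp((d−d₀)/λ)). Restraint lengths d₀
  are 30 Å (LC-SDA, DSS) and 25 Å (EDC). ψ (default 0.05, bounded to [0, 0.5])
  floors the cost of an unsatisfiable link at −log ψ; it is a fixed parameter,
  not a sampled nuisance. λ (default 2 Å) is the logistic softness and stands
  in for the positional uncertainty of the crosslinked site; the mapping to a
  per-link σ is not one-to-one. Links designated inter-protein by the isotope
  doublet analysis admit only assignments on *different* chain copies —
  without this the joint-copy ambiguity lets an inter link be satisfied within
  one copy and dimer recovery degenerates.
* **Excluded volume**: half-harmonic overlap penalty, k=1 Å⁻², on scoring-bead
  pairs that are neither bonded nor in the same rigid body.
* **Connectivity**: harmonic upper bound on every sequence-adjacent bead pair,
  center c = 2(r_i + r_j), k=1 Å⁻².
* **EM**: w·(1−cc), w=100, with cc the Gaussian-overlap cross-correlation
  computed in closed form between the mobile domain's bead GMM (one isotropic
  component per bead, weight = mass, variance = radius²) and a GMM fitted to
  the experimental map. Only the mobile domain is compared because the MT
  contribution is erased from the map. Map GMMs are fitted by sampling voxel
  centers with probability proportional to density above a floor of 3× the
  MAD-based noise scale (needed for determinism), jittering within the voxel,
  and running scikit-learn's EM with a fixed random state.

## Sampling

Gibbs-style Metropolis Monte Carlo: one sweep proposes, for every mobile rigid
body, a rotation about its centroid (axis uniform on the sphere, angle uniform
up to 0.5 rad, composed via unit quaternions to stay regular at zero angle)
plus a translation uniform in a 4 Å ball, and for every free bead a 4 Å-ball
translation. Replica exchange uses a geometric temperature ladder from 1.0 to
2.5 by default (the ladder is a package choice; replica counts have precedent
but temperatures do not), adjacent-pair swaps every 10 sweeps with probability
min(1, exp((1/T_i − 1/T_j)(S_i − S_j))). Configurations are saved every 10
sweeps from the coldest replica only, so saved models approximate the target
distribution; the choice is recorded in each model's provenance. Independent
runs take seeds spawned from the master seed and are labeled for A/B
splitting. A fixed seed reproduces the saved ensemble exactly, and one replica
reduces bit-for-bit to plain Metropolis.

Problem sizes: the synthetic scenarios run 4 runs × 4 replicas × 1500 sweeps
(stage 1) and 2 × 3 × 800 (dimer stages), a desk-scale regime in which the
stage-1 posterior is already unimodal (sampling precision 6–8 Å). A
full-scale profile (10 runs × 30 replicas × 3×10⁵ sweeps) is shipped as a
constant for production runs against real deposited data.

## Ensemble analysis

Models are filtered to the best half by score and to poses whose mobile-domain
centroid sits nearest an *interior* junction — edge sites would be occupied by
tubulin in a full microtubule. Clustering is leader-style on score-sorted
models: a model joins the first cluster whose founding model is within the
RMSD threshold; centroids (member with minimal mean RMSD to members) are
recomputed once at the end. All RMSDs are computed in the fixed-lattice frame
without superposition, since the lattice never moves. Cluster precision is the
mean member RMSD to the centroid (a two-member cluster at RMSD d has precision
d/2 by construction).

Sampling precision splits the runs into two halves and, at each threshold of
an increasing grid, clusters the pooled ensemble and tests the two halves'
cluster populations for homogeneity: pass requires χ² p > 0.05, Cramér's V
< 0.10, and ≥ 80 % of models in clusters containing both halves (the published
convergence-protocol defaults; a single pooled cluster passes trivially). The
precision is the smallest passing threshold, and the ensemble is clustered at
that threshold for reporting. Cluster precisions are reported on the filtered
ensemble, with the unfiltered top-cluster precision retained alongside for
comparison.

Crosslink satisfaction uses the minimum assignment distance per model and the
strict thresholds d < 35 Å (LC-SDA/DSS) or d < 30 Å (EDC); distances exactly
at the threshold do not count. Cluster-level satisfaction is any-member.
Localization densities Gaussian-splat each member's component beads
(σ = bead radius) and normalize so the map integrates to the component mass;
maps are written as MRC through gemmi.

## Isotope doublets

Under 1:1 ¹⁴N/¹⁵N mixing a crosslinked peptide pair appears as up to four
species (LL, LH, HL, HH). Envelopes are computed by exact polynomial
convolution of per-element isotope distributions on a 10⁻⁶ Da grid (rounding
error < 10⁻⁴ Da for hundreds of atoms), with heavy peptides using a binomial
¹⁵N distribution at the stated enrichment (default 0.99, matching the >99 %
incorporation regime). The linked-form crosslinker compositions are derived
from vendor reagent formulas — LC-SDA: C₁₀H₁₄O₂ after NHS loss and diazirine
photolysis; DSS: C₈H₁₀O₂ after two NHS losses; EDC: zero-length, net −H₂O —
and are overridable. Observed envelopes are charge-deconvoluted and rebinned
at 0.01 Da (instrument binning is otherwise unspecified), decomposed onto the
four species by nonnegative least squares, and classified by the inner:outer
ratio (w_LH + w_HL)/(w_LL + w_HH): < 0.2 intra, > 0.8 inter, else mixed. The
category boundaries are qualitative in origin; both are exposed as
configuration. The call is scale-invariant by construction.

## Synthetic data

The generator emulates the study's inputs at toy scale with full ground truth:
pseudo-tubulin monomers are 40-residue self-avoiding Cα walks confined to a
~34 Å ellipsoid, recentered so replicated copies land exactly on the lattice
grid (lateral spacing 52 Å, longitudinal dimer repeat 82 Å — near canonical
geometry, configurable, and fixture parameters rather than claims). The mobile
domain is docked at a chosen interior junction at the smallest height with no
excluded-volume overlap. True crosslinks are drawn uniformly from
inter-component residue pairs closer than d₀ in the true pose; decoys are
drawn from all pairs regardless of distance and flagged. Crosslinks to the
lattice record their chain copy, emulating modeling against the minimal repeat
unit where every tubulin position is distinct — entity-level links on a patch
of identical monomers would be junction-degenerate by symmetry. DCX–DCX links
in the dimer scenarios are entity-level (copy-ambiguous) but inter-copy-only,
as the doublet analysis licenses. Density maps are Gaussian splats of the
mobile domain only, plus optional white noise; MS1 observations mix the four
species envelopes (intra 1:0:0:1, inter 1:1:1:1, mixed 2:1:1:2 by default)
plus Gaussian noise. Every generator is a pure function of its parameters and
seed.

What the toys do *not* capture: real tubulin surface detail and residue
chemistry (crosslinkable residues are not restricted to K/D/E), kinetic
trapping of the crosslinker, peak-picking and retention-time effects in MS1,
and the curved microtubule wall. Passing tests therefore demonstrate that the
machinery — scoring, sampling, convergence analysis, classification — is
correct and self-consistent, not that any biological conclusion follows from
real data.

## Design notes and limitations

* The Bayesian crosslink functional form (two-state ψ-mixture over a logistic
  satisfaction probability) is fixed here because it reproduces the intended
  behavior — a distance restraint with a saturating uncertainty floor — and is
  analytically testable at its midpoint and limits.
* Because crosslinks are distance *upper* bounds, a more compact conformation
  can always satisfy links generated from a more extended truth. On the blob
  toys the globular and open CDC forms therefore tie on satisfaction, and the
  scenario comparison reports "indistinguishable" — consistent with
  satisfaction differences being weak discriminators in this regime. Form
  preference, where it exists, shows up in cluster morphology rather than
  utilization rates.
* Degenerate inputs are handled explicitly: identity lattice transforms raise
  a steric-collapse error; an empty floored map, zero NNLS weights, a single
  sampling run, and anchor geometries on patches without two interior
  junctions all raise informative errors; when edge filtering eliminates an
  entire run, sampling precision is reported as unmeasurable (infinite) rather
  than raised.
* ψ/σ nuisance sampling, atomic detail, B-factors, the 13-protofilament closed
  tube, and A-lattice seams are out of scope.
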