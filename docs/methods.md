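# Methods

## Problem and approach

Predicted protein complexes come with a per-residue confidence estimate
(pLDDT, 0–100, stored in the PDB B-factor column), but a confidently
predicted pair of monomers can still be docked at the wrong site.  This
package implements a confidence-gated docking protocol around that
observation:

1. **Gate.** The *interface-pLDDT* — the mean pLDDT over interface residues
   (any heavy atom within 8 Å of the partner) — decides whether the
   predicted orientation is trustworthy.  At or above the threshold
   (default 85) the pose is only refined locally; below it a global
   rigid-body search is launched from randomized orientations.
2. **Sampling.** A temperature replica-exchange Monte Carlo engine samples
   rigid-body poses (global: 4 Å translations / 8° rotations; local: 1 Å /
   3°), with backbone torsion moves directed at *mobile residues*
   (contiguous runs of pLDDT < 80) mixed in at a 3:1 backbone:rigid ratio
   during local refinement.
3. **Selection.** Global decoys are clustered (energy-ranked greedy
   clustering by ligand-RMSD) to at most five representatives; each is
   refined locally; final models are ranked by interface score (bound
   minus separated energy).

Evaluation against a reference complex uses the standard docking-quality
metrics: fnat, interface RMSD (Irms), ligand RMSD (Lrms), their DockQ
combination, and CAPRI quality classes.

## Models and formulas

**LDDT.**  Computed on Cα atoms.  For ordered residue pairs (i, j), i ≠ j,
whose *reference* Cα distance is below the inclusion radius (10 Å), the
pair score is the fraction of tolerances {0.5, 1, 2, 4} Å that the distance
deviation |D_ref − D_model| stays within; the global score averages pair
scores over all included pairs, and the per-residue score restricts the
average to pairs involving that residue.  Because inclusion is decided by
reference distances only and i = j is excluded, the score is
superposition-free and exactly 1 for a model identical to its reference.
The per-residue mask is implemented as "both residues mapped and i ≠ j".

**Per-residue RMSD.**  A single global Kabsch superposition on all mapped
Cα atoms (not per-domain), then the per-residue Cα deviation.  This makes
the metric sensitive to domain motions, deliberately complementing LDDT.

**Residue mapping.**  Per-chain global sequence alignment (match +1,
mismatch −1, gap −2) with unaligned termini trimmed and gapped positions
excluded; chains pair by label when shared, by order otherwise.  Below 30%
identity the mapping is refused as a probable wrong pairing.

**DockQ.**  DockQ = [fnat + 1/(1+(Irms/1.5)²) + 1/(1+(Lrms/8.5)²)] / 3,
with the CAPRI conventions: contacts are cross-partner residue pairs with
any heavy-atom distance ≤ 5 Å; the Irms interface is reference residues
with any heavy atom within 10 Å of the partner, superposed on backbone
(N, Cα, C, O) atoms; Lrms superposes on the receptor backbone only.
Class bins: DockQ ≤ 0.23 incorrect; (0.23, 0.49] acceptable; (0.49, 0.8)
medium; ≥ 0.8 high.  The boundary choices (0.23 itself incorrect, 0.8
itself high) follow the published bin edges verbatim; the alternative
reading in which exactly 0.23 is acceptable is noted but not adopted.

**Metropolis and replica exchange.**  Moves are accepted with probability
min(1, exp(−ΔE/kT)); adjacent rungs i, j swap configurations with
probability min(1, exp((β_i − β_j)(E_i − E_j))).  The default ladder is
kT = 1.5, 3.0, 5.0 kcal/mol with eight trajectories.  Swaps are attempted
every 50 steps on alternating even/odd adjacent pairs; snapshots of the
coldest rung are recorded every 10 steps.  Each trajectory draws from an
independent child stream of the master seed, so runs are bitwise
reproducible and trajectories are order-independent.

**Moves.**  Rigid translations are Gaussian per axis with σ chosen so the
*expected magnitude* equals the schedule's translation size (σ =
trans_mag·√(π/8)); rotations use a Gaussian angle (σ = rot_mag) about a
uniform random axis through the ligand centroid.  The rotation is stored
as an orthonormal matrix and re-orthonormalized on every composition, so
intra-partner geometry is conserved to < 1e-9 Å over arbitrarily long
trajectories.  Backbone moves add Gaussian φ/ψ offsets (σ = 3°) to one
randomly chosen mobile segment with downstream propagation along the chain
and **no loop closure** — a deliberate simplification of Backrub/kinematic
closure movers; it preserves bond geometry inside the moved segment but
lets the chain tail swing, which is acceptable for short mobile segments
and documented as a divergence from the full protocol.

**Scoring.**  The all-atom energy function of the full protocol is out of
scope; scoring is a pluggable `pose -> energy` callable.  The default is a
coarse Cβ contact potential (harmonic repulsion k=5 below 4 Å, −1 per
cross-partner Cβ pair in [4, 8) Å).  The interface score subtracts the
energy of the same pose with the ligand displaced 500 Å along the
centre-of-mass axis, so for pairwise-additive scorers it isolates the
binding contribution.

## Synthetic data

The fixture generator builds two-partner complexes from ideal backbone
internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, standard
angles; α-helical, extended, or random torsions), with explicit Cβ so the
contact definitions never hit the glycine fallback unless requested.  The
partners are packed side by side — ligand long axis aligned with the
receptor's, seed-dependent spin, flip and approach azimuth — and slid to a
4 Å closest-approach gap.  This construction guarantees, for every seed, a
clash-free native pose with a genuine contact patch (≥ 5 Cβ pairs within
8 Å), which random relative orientations do not.

Decoys at a requested ligand-RMSD combine a random rotation about the
ligand centroid with a translation solved orthogonally to the mean
rotational displacement, achieving the target Lrms within 10%.

The planted funnel landscape is
`default_score(pose) − depth·exp(−Lrms²/(2·width²))` with width 8 Å and
depth 500.  The width is of the order of a partner's size, so the funnel
gradient is felt across the accessible pose space; the depth is large
relative both to the temperature ladder and to the measured spread of the
contact term among near-native rigid poses (~10 score units), which keeps
the combined minimum within a fraction of an ångström of the planted pose.

What the toy does *not* emulate: side chains beyond Cβ, realistic energy
surfaces, sequence effects, multi-chain partners, or the error modes of
real predicted structures beyond piecewise pLDDT profiles.  Passing the
recovery tests therefore validates the *sampling and pipeline logic* —
that the engine finds and holds a funnel minimum it is given — not docking
accuracy on real proteins.

## Problem sizes and numerical choices

Simulations in the shipped tests and the acceptance script use the default
toy (24 + 20 residues, 5 atoms/residue), 8 trajectories × 3 rungs × 5000
global steps, and 2000-step local refinements with 2 trajectories per
cluster representative — sizes chosen so a complete validation runs on a
single CPU in minutes while still exercising every stage at the published
move magnitudes and temperatures.

Other choices of note:

* pLDDT inputs with max ≤ 1.0 are rescaled ×100 with a warning; values
  outside [0, 100] are an error (never clamped).
* An empty predicted interface yields a sentinel interface-pLDDT of −1 and
  always gates to GLOBAL: no interface is the strongest evidence of a
  failed docking prediction.
* The gate boundary is LOCAL at exactly 85 (the ≥ branch); the threshold
  is configurable.
* Mobile segments require a minimum run of 3 residues (shorter runs give
  the torsion mover no useful lever arm); configurable.
* Greedy clustering keeps the lowest-energy 20% of decoys and uses a 5 Å
  ligand-RMSD radius; fewer than five clusters simply all proceed.
* Altloc: highest occupancy wins, first on tie.  Multi-model files: model
  1 only.  Hydrogens are ignored everywhere.
* Ranking ties break by total energy, then provenance order, keeping
  ranking deterministic.

## Known limitations

* Backbone moves have no loop closure and no side-chain repacking; local
  refinement is therefore much coarser than the full published protocol.
* The default scorer is a toy potential; quantitative energies and funnels
  on real complexes require plugging in a real score model.
* LDDT is Cα-only by design (the defining equations are written on Cα);
  all-atom LDDT would score side-chain environments differently.
* The residue mapper assumes colinear chains and refuses below 30%
  identity rather than attempting structural alignment.
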