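# Methods

## Numbering convention

All residue selections use a single *continuous* 1-based index obtained by
concatenating chains in file order. For a homodimer of 366-residue monomers
this makes residue r of the second monomer address as r + 366, which is how
the default plane triplets relate (75/169/267 ↔ 441/535/633). Author
numbering, including gaps and insertion codes, is preserved in a per-residue
mapping table (`Structure.residue_table`) so users can audit the
correspondence — structures deposited with different author numbering (e.g.
the DNA-bound clamp) must be checked there rather than assumed to line up.
Alternate locations are resolved by highest occupancy (ties fall to the
first listed, conventionally 'A'). One deliberate exception to the
continuous convention: the sequence-neighbour exclusion in the restraint
builder uses author numbering within a chain, because a numbering gap means
unresolved residues, not a covalent bond, and cross-chain pairs are never
neighbours.

## Aperture: harmonic mean of interface distances

The interface metric averages the *inverses* of the frozen contact-pair
distances and reports the inverse of that average — the harmonic mean
`H = n / Σ 1/dᵢ`. This keeps the metric in Å (H = d for a single pair, and
H ≤ arithmetic mean always) while strongly damping the contribution of a few
very long distances once the joint has separated, which is the reason for
averaging inverses in the first place. The arithmetic mean is available via
``aperture(..., mean="arithmetic")`` for comparison, but the harmonic form
is primary. The pair set is *frozen* from the reference
frame: pairs are the CA pairs (one per group) within the cutoff (default
8 Å) in the reference structure, and the same pairs are measured at every
later frame even when they exceed the cutoff — a drifting pair list would
make the series incomparable across frames.

## Interplanar angle and orientation

Each subunit's plane is fit through three CA atoms; the normal is oriented
by the right-hand rule on the ordered triplet, and the angle between the two
oriented normals is reported in [0, 180] *without* folding to [0, 90]. The
orientation matters: for a planar ring whose two triplets are listed in
mirrored traversal order the normals are antiparallel, so the closed clamp
reads ≈180° (the crystal structure reads about 172°), and folding would
destroy that signature. Out-of-plane motion is quantified as the absolute
deviation of the angle from its reference value — taken from frame 0 unless
overridden — rather than from the ideal 180°, since the experimental closed
state is itself 8° off planar. Collinearity is rejected below a triangle
area of 1e-6 Å².

## RMSD

Backbone RMSD (CA-only by default) uses the closed-form Kabsch/quaternion
superposition from `scipy.spatial.transform.Rotation.align_vectors`, which
enforces a proper rotation (det = +1). Residuals are recomputed explicitly
after applying the fitted rotation instead of using the solver's reported
root-sum-square, which suffers ~1e-6 Å cancellation noise near exact
overlap; the recomputed form is accurate to machine precision there,
which the rigid-invariance tests rely on.

## Event detection and classification

Opening events are found by a two-threshold (hysteresis) state machine on
the aperture series: open at the first frame strictly above θ_open while
closed, close at the first subsequent frame strictly below θ_close, with
θ_close < θ_open required. Ties at a threshold keep the current state, so
the detector is deterministic and events never overlap. Defaults:
θ_open = 15 Å — the smallest opening amplitude reported for the clamp, with
observed openings ranging to ~80 Å — and θ_close = 10 Å, roughly twice the
closed-state aperture fluctuation seen on synthetic data and far enough
below θ_open that per-frame noise with σ < (θ_open − θ_close)/4 cannot
cause chatter. An event still open at the last frame is reported with no
close frame and never counted as reversible. Mode classification is by the
*maximum* angular deviation during the event (strictly greater than 30°
→ out-of-plane): the mode is diagnosed by the extreme excursion, and
reported deviations of clamp openings are extremes ("as high as 30°"), so a
mean would systematically under-call. Dissociation — both interfaces beyond
θ_diss = 100 Å for ≥10 consecutive frames — takes precedence over any event
count in walker classification, since a dissociated dimer's later "events"
are meaningless. θ_diss and the window are qualitative choices; dissociation
is an irreversible, unambiguous state and the results are insensitive to
them over wide ranges.

## Clustering

Frames are clustered agglomeratively on the full pairwise backbone-RMSD
matrix with average linkage by default (single and complete linkage are one
argument away; average is the conventional compromise for conformational
ensembles). Labels are renumbered by descending population with ties broken
by earliest frame, populations are frame fractions (summing to 1), and each
cluster's representative is its medoid — the member frame with minimal mean
RMSD to the rest of the cluster. The O(n²) matrix limits this to modest
frame counts, which suits its role of summarizing strided production
trajectories.

## Restraint network and replica-exchange bookkeeping

The tertiary-structure restraint set places one flat-bottom distance
restraint on every CA pair within 8 Å in the initial structure, excluding
intra-residue and sequence-neighbour pairs (|Δresidue| < 2 along the chain)
whose distances are fixed by covalent geometry anyway. The functional form
has four knots r1 ≤ r2 ≤ r3 ≤ r4: zero on [r2, r3], quadratic shoulders
k(r−r2)²/k(r−r3)² out to r1/r4, and linear tails beyond matching value and
slope — C¹ everywhere, with only linear growth for gross violations so a
single bad restraint cannot dominate. Knots are centred on the reference
distance d as (d−2Δ, d−Δ, d+Δ, d+2Δ), floored at 0. Δ = 0.5 Å and
k = 250 kcal·mol⁻¹·Å⁻² are package defaults chosen to hold a fold together
at 500 K while tolerating thermal breathing; both are configurable and are
conventions of this toolkit, not measured quantities. Interface restraint
sets are generated by the same builder applied to the two interface residue
groups.

Temperature ladders are geometric by default (constant Tᵢ₊₁/Tᵢ, endpoints
exact — e.g. 50 replicas spanning 300–500 K), the standard choice for
roughly uniform neighbour acceptance. The Metropolis probability uses
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹. Exchange logs record attempted swaps of
*adjacent* replicas (alternating even/odd pairings in the synthetic
generator); demultiplexing replays accepted swaps from the initial
walker→replica bijection, a swap at step s taking effect from step s
onward, and asserts the assignment stays a permutation. Round trips are
completed bottom→top→bottom traversals. The replica-exchange *sampler*
itself (dynamics, Hamiltonian scaling, restraint-subset selection) is out
of scope: only the restraint math and the bookkeeping live here.

## Synthetic toy clamp

The generator emulates the geometry that the indicators consume, nothing
more: two semicircular arcs of CA-like beads (default 20 per arm, radius
30 Å, interface half-gap 4° giving ~4.2 Å junction chords, comparable to a
closed protein interface contact) in the z = 0 plane. Opening events rotate
one arm rigidly about the hinge at the opposite interface with a linear
ramp up to the amplitude and back: about the z axis for in-plane mode
(coplanarity exactly preserved), about the in-plane ŷ axis through the
hinge for out-of-plane mode — ŷ rather than x̂ because rotation about the
interface axis x̂ would *shrink* the far junction's chord instead of opening
it. The angular deviation then equals the planted rotation angle exactly,
so out-of-plane events must be planted with amplitude > 30° to be
classified as such. Noise is i.i.d. isotropic Gaussian per coordinate per
frame — the simplest model that exercises the hysteresis gap; it has no
temporal correlation, no anisotropy and no internal flexibility, so passing
recovery tests demonstrates detector correctness under the stated
signal-to-noise conditions, not robustness to real-MD artifacts (correlated
drift, partial unfolding, loop breathing). Walker cohorts are generated
directly as aperture/deviation series with rectangular event pulses whose
open/close frames coincide with the detector's crossing convention, so
exact ±1-frame recovery is a meaningful check; class counts follow
largest-remainder rounding of the requested proportions so stated cohort
compositions are hit exactly. All generators are deterministic in their
seed and return their schedule as ground truth.

## Problem sizes and determinism

The shipped checks run on 40-bead rings, 160-frame trajectories, 50-walker
cohorts (three seeds), 8-replica × 1000-attempt exchange logs (five seeds)
and 6-frame clustering problems — sizes at which every oracle (brute-force
pair enumeration, exhaustive 2-partitions, replica-centric replay,
1-D 0.1° rotation grids) is exact and the whole suite runs in seconds.
Every stochastic path takes an explicit seed; file outputs format floats at
6 significant digits so re-runs are byte-identical.

## Known limitations

- No mmCIF or compressed trajectory formats; PDB and a plain-text frame
  dialect only. No bond inference, hydrogens or force-field topology.
- The aperture depends on the user's interface residue groups; the
  `--auto-interface` convention (10 residues flanking each inter-chain
  junction in continuous numbering) is a fallback for ring topologies
  deposited as two chains, not a contact-based interface definition.
- Event thresholds are operational definitions: published walker-fraction
  statistics from large REMD ensembles cannot be reproduced without the
  original criterion and sampling, and no attempt is made to do so.
- No kinetics: frame indices are not physical time, and no rates, lifetimes
  or free energies are estimated.
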