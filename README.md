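# clampkit

Trajectory-analysis toolkit for ring opening in DNA sliding clamps.

The bacterial β-clamp (the β subunit of *E. coli* DNA polymerase III, PDB
1MMI unbound / 3BEP DNA-bound) is a circular homodimer that encircles
double-stranded DNA and keeps the polymerase processive. Before DNA can be
loaded, the ring must transiently open at one of its two monomer–monomer
interfaces. Simulations that probe this rare event — plain MD, coarse-grained
models, or restraint-guided temperature/Hamiltonian replica exchange — all
produce the same analysis problem: given trajectories, *when* does the ring
open, *how wide*, *in* or *out of* the clamp plane, and does it close again?
clampkit answers those questions, and also generates the flat-bottom
restraint networks and replica-exchange bookkeeping such simulations use.

## What it computes

For a two-subunit ring with CA coordinates, three indicators per frame:

- **Aperture** of each interface: the harmonic mean of the frozen set of
  reference CA–CA contact-pair distances,
  `H = n / Σ 1/dᵢ` — the inverse of the averaged inverse distances, which
  damps the influence of a few very long distances once the joint separates.
  Contact pairs are all CA pairs with one atom in each interface residue
  group within a cutoff (default 8 Å) in the reference frame.
- **Interplanar angle** between the oriented planes through three CA atoms
  of each subunit (defaults 75/169/267 and 441/535/633 in continuous
  numbering, i.e. residue r of monomer 2 is r + 366). The closed, nearly
  planar ring sits near 180° (≈172° in the crystal structure); the absolute
  deviation from the reference angle diagnoses out-of-plane motion.
- **Backbone RMSD** to the reference after optimal rigid superposition.

On top of the per-frame series:

- **Opening events** via hysteresis thresholding: open when the aperture
  exceeds θ_open (default 15 Å), close when it drops below θ_close
  (default 10 Å < θ_open, so noise cannot chatter). Events are classified
  `in_plane`/`out_of_plane` (max angular deviation vs 30°) and
  reversible/unterminated; walkers whose both interfaces stay beyond 100 Å
  for 10 frames are flagged `dissociated`.
- **Hierarchical clustering** of frames on the pairwise-RMSD matrix
  (average linkage), with population fractions and medoid frames.
- **Replica-exchange machinery**: flat-bottom CA restraint networks (every
  CA pair within 8 Å, four knots, quadratic shoulders, linear tails),
  geometric temperature ladders (e.g. 50 replicas, 300–500 K), the
  Metropolis swap probability `min(1, exp[(βᵢ−βⱼ)(Eᵢ−Eⱼ)])`, walker
  demultiplexing from exchange logs, and round-trip counting.
- **Synthetic toy clamps**: a two-arm bead ring with planted opening events
  of known frame, amplitude and mode, plus synthetic exchange logs with
  known walker paths — every analysis stage is testable without downloads.

## Worked example

Generate a toy-clamp trajectory with two planted openings — an in-plane one
at interface 1 (frames 20–60) and an out-of-plane one at interface 2
(frames 100–140), both 60° of arm rotation with 0.2 Å coordinate noise —
then analyze it:

```sh
clampkit synthesize --beads-per-arm 20 --radius 30 --noise-sigma 0.2 \
    --n-frames 160 --seed 11 \
    --event 1:20:60:60:in_plane --event 2:100:140:60:out_of_plane \
    --exchange-log --outdir bundle
clampkit analyze --structure bundle/toy_clamp.pdb \
    --trajectory bundle/trajectory.txt --auto-interface \
    --triplet-a 1,10,20 --triplet-b 40,30,21 --outdir analysis
```

which prints `2 events (reversible_opener); outputs in analysis`, and
`analysis/events.csv` contains:

```
walker,interface,open_frame,close_frame,peak_aperture,peak_deviation,mode
0,interface1,24,59,63.4784,1.21325,in_plane
0,interface2,105,138,59.7436,59.1948,out_of_plane
```

Both planted events are recovered: the detector fires a few frames after the
scheduled open frame (the aperture must ramp past 15 Å) and closes before
the scheduled close; the in-plane event keeps the angular deviation near 0°
while the out-of-plane one peaks near the planted 60° rotation, and both
peak apertures sit in the tens of Å, the scale a clamp must reach to pass
double-stranded DNA. `analysis/metrics.csv` holds the per-frame series, and
`analysis/summary.json` echoes the full configuration. Demultiplexing the
bundled synthetic exchange log,

```sh
clampkit demux bundle/exchange_log.tsv --out paths.csv
```

prints `8 walkers over 200 steps; round trips: [0, 1, 0, 0, 0, 1, 0, 0]`.

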