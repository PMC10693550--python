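# ccphase

Coarse-grained simulation and analysis of coiled-coil driven liquid–liquid
phase separation (LLPS).

Designed proteins built from coiled-coil (CC) dimerization modules — short
heptad-repeat peptides joined by flexible Gly/Ser linkers — form synthetic
condensates whose behaviour is governed by a small set of design rules:
how many CC "stickers" a chain carries, how they are arranged, how strongly
and in which orientation (parallel vs antiparallel) each pair binds, and
whether a partner chain can satisfy *all* of a chain's stickers at once
(which produces inert molecular dimers instead of a percolating network).
`ccphase` implements a sticker–spacer bead model of these designs — one
bead per residue, registry- and orientation-gated sticky attraction between
complementary coil beads (σ = 0.570 nm, ε = 7.5 kJ/mol), strict 1:1 valence
saturation — together with the slab phase-coexistence workflow and the
analyses used to call each design **condensate**, **dimer-poisoned**, or
**diffuse**: density profiles along the slab axis, molecular cluster-size
distributions, MSD-based diffusion with bootstrap errors, and per-coil
engagement statistics.

The model's temperature scale is calibrated against the measured
dissociation constants of the isolated coil pairs (5.9 µM and 2.3 µM for
the 4-heptad pairs; 2.3 mM and 0.34 mM for the 3-heptad pairs); see
`docs/methods.md` for the model, assumptions, and desk-scale choices.

## Worked example

Parse a two-component design, run the slab workflow, and classify it:

```python
from ccphase import (SystemSpec, parse_construct, run_slab,
                     density_profile, cluster_distribution, classify_phase)
from ccphase.slab import DESK_PROTOCOL

system = SystemSpec(
    components=[(parse_construct("Cit-(S1h-S3h)3-gs"), 6),
                (parse_construct("BFP-(S2h)3(S4h)3-gs"), 6)],
    temperature=DESK_PROTOCOL.temperature,
    seed=2,
)
result = run_slab(system, DESK_PROTOCOL)
traj = result.trajectories[0]
call = classify_phase(density_profile(traj), cluster_distribution(traj))
print(call.label, round(call.largest_cluster_fraction, 2),
      round(call.dimer_dominance_fraction, 2))
```

```
condensate 1.0 0.0
```

The alternating chain `(S1h-S3h)3` cannot be fully satisfied by the
clustered partner `(S2h)3(S4h)3`, so dangling stickers crosslink chains
into one cluster holding all twelve chains — a condensate.  Swapping the
partner for the *matched* arrangement `(S2h-S4h)3` lets a single partner
chain zip up every sticker; the same pipeline (same seed) then reports
`dimer 0.45 0.8`: a gas in which size-2 clusters are the dominant species
in 80% of frames — dimer poisoning.  Individual desk-scale runs are small
(12 chains, ~3 ns) and sit near the percolation threshold, so panel
evaluations vote over three seeds per design.

The same machinery is exposed on the command line:

```bash
ccphase build "Cit-(S1h-S3h)3-gs" --json   # 166-bead topology
ccphase params show                        # force-field constants
ccphase slab run --construct "Cit-APPAPAPPAP-gs" --seed 1 --out run1/
ccphase analyze run1/production.xyz --topology run1/topology.json
ccphase panel --seed 1 --out panel_out/    # full design truth table
ccphase calibrate --temp 575 --temp 625 --temp 675
```

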