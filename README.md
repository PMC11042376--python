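# mitofold

Simulation and analysis toolkit for studying how loop-extruding SMC
complexes (condensin I, condensin II, cohesin) fold interphase chromatin
into mitotic chromosomes. It is aimed at chromosome-organization groups who
want to test "rules of engagement" hypotheses — what happens when a
translocating condensin meets a cohesin (unloading, pushing, bypassing or
stalling) — and to interpret mitotic Hi-C contact maps with coarse-grained
chromatid models.

The package covers one pipeline, end to end and entirely on synthetic
inputs:

1. **1D loop extrusion** (`mitofold.extrusion`): a discrete lattice
   (1 kb/site) on which two-sided SMC motors extrude loops at configurable
   speeds and densities, with a collision-policy matrix over species pairs
   (`bypass | stall | unload_obstacle | push_obstacle | unload_self`),
   orientation-gated CTCF barriers, and loading/unloading kinetics.
2. **Coarse-grained 3D chromatids** (`mitofold.chromatid`): loop arrays are
   folded into bottlebrush chromatids at 10 kb/bead. Free parameters: the
   average loop size ℓ (bp), the inter-condensin gap g (nm), and the linear
   density ρ (Mb/µm along the axis); fixed from experiment: the helix turn
   length T (Mb, from the second diagonal of Hi-C maps) and the volume
   density φ (Mb/µm³, from electron microscopy). Condensin II chromatids
   are cylinders whose scaffold is nudged onto an irregular helix with
   winding number L/T and pitch T/ρ; condensin I chromatids are weakly
   stretched random-walk brushes with an imposed end-to-end extension.
3. **Contact analysis** (`mitofold.contacts`): contact maps and P(s)
   contact-probability curves from bead ensembles; the log-derivative
   d log P / d log s, loop-size estimation from its loop feature;
   detection of the periodic second/third/fourth diagonal bands of mitotic
   maps; compartment (checkerboard) and dot (CTCF–CTCF pileup) strengths
   normalized to a G2 reference.
4. **Model fitting** (`mitofold.fitting`): grid search of (ℓ, g, ρ) against
   a target P(s) with an RMS log10 objective, plus the nested
   condensin II + condensin I combination model.
5. **Speed estimators** (`mitofold.kinetics`): the extrusion-speed
   arithmetic used on synchronized mitotic-entry time courses — loop size
   over elapsed time, loop-size increments, gap-closure capacity, spiral
   (helix-period) growth rates, and the projected-area→volume conversion.
6. **Synthetic data** (`mitofold.synthetic`): seeded generators for every
   input — G2-like CTCF/cohesin landscapes, exponential loop arrays, A/B
   compartment tracks, cohesive-link sets, planted-signal contact maps and
   noisy target P(s) curves.

## Worked example

```python
import numpy as np
import mitofold as mf

# In-vivo speed arithmetic: the helix period (second-diagonal position)
# grows from 4.0 to 6.1 Mb between 15 and 30 min after release from G2.
est = mf.spiral_growth_rate(mf.TimeSeries([15, 30], [4.0, 6.1], "period_mb"))
print("WT spiral growth:", est.rounded, "kb/s")

# A 400 kb loop extruded within 5 min of condensin activation:
print("endpoint:", mf.speed_endpoint(400.0, 300.0).rounded, "kb/s")

# Condensin II-only chromatid model (400 kb loops, 80 nm gaps, 17 Mb/turn,
# 44 Mb/um^3): ensemble P(s) and its periodic diagonal bands.
params = mf.ChromatidParams(**mf.CONDENSIN_II_BEST_FIT)
ps = mf.simulate_ps(params, genome_mb=100, replicates=20, seed0=1,
                    bins_per_decade=35)
bands = mf.detect_periodic_diagonals(ps)
print("diagonal bands (Mb):", np.round(bands.positions_mb, 1))
print("winding number:", round(params.winding_number(100e6), 1),
      "turns; pitch:", round(params.pitch_nm), "nm")
```

prints

```
WT spiral growth: 2.3 kb/s
endpoint: 1.3 kb/s
diagonal bands (Mb): [16.5 34.4 49.2]
winding number: 5.9 turns; pitch: 400 nm
```

The spiral growth rate (2.3 kb/s) and endpoint speed (1.3 kb/s) bracket the
1–3 kb/s range of condensin extrusion in vivo. The helical chromatid model
puts its second diagonal band at ~16 Mb — one helical turn of chromatin —
with the third and a faint fourth band at multiples of it (~34 and ~49 Mb),
the signature of contacts between loops one, two and three gyres apart.

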