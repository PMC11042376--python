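# Methods

## 1D loop-extrusion engine

The chromosome is a lattice of sites, 1 kb/site by default. A lattice site
is the resolution at which SMC positions, collisions and CTCF barriers are
meaningful here; 1 kb keeps 10–100 Mb runs tractable in pure Python while
resolving loops of tens of kb. Geometry at sub-kb scale (the 200 bp/10 nm
nucleosome fiber) only enters the 3D builders through derived constants.

Extruders occupy two sites (left and right leg) and are two-sided and
symmetric: each leg translocates outward at the species' per-leg speed, so
the loop grows at twice that speed. Speeds are configured in kb/s; the time
step is chosen as (site size)/(fastest per-leg speed), so the fastest legs
move deterministically one site per step and slower species move
probabilistically. A configuration whose per-step move probability would
exceed 1 is rejected with a message to use a smaller time step.

Each step, all mobile legs are visited in a freshly shuffled order (the
seeded tie-break when two legs contest one site). A leg attempting to enter
an occupied site consults the collision policy for the ordered pair
(moving species, occupant species):

* `bypass` — the leg steps over the occupant (both stay bound); chained
  occupants are resolved recursively;
* `stall` — the leg stays put and is marked stalled; stall status is
  re-evaluated every step, so a leg resumes if its obstacle disappears;
* `unload_obstacle` — the occupant (a whole extruder, if the occupant is a
  leg) is removed and the mover advances;
* `push_obstacle` — the contiguous chain of occupants is displaced one
  site; a chain containing a cohesive cohesin is unpushable by default
  (it tethers the sister chromatid; configurable), and pushing against the
  chromosome end converts to a stall;
* `unload_self` — the mover's complex is removed.

Chromosome ends always stall. Default policy: condensin–condensin
encounters stall (this is what makes loop arrays consecutive and
non-overlapping, and it applies between condensin I and II as well — the
conservative default where the evidence fixes only the
condensin II–condensin II case); condensins bypass cohesive cohesin and
ignore CTCF; extrusive cohesin is stalled by CTCF only when it approaches
the motif-facing side (a `+` site blocks leftward motion, a `-` site
rightward, so loops form between convergent pairs). A pushed cohesin loses
its CTCF anchoring simply by being displaced off the site. Unloaded
extrusive cohesin does not rebind during mitotic runs, and background CTCF
loss is modeled as first-order removal of barrier sites.

The four prophase scenarios (`unload`, `push`, `bypass`, `stall`) are
presets that change only the condensin-vs-extrusive-cohesin rule. The
prophase driver places extrusive cohesins one site inside each convergent
CTCF pair of the G2 fixture (the dots), loads condensin II at t = 0
(2.5 complexes/Mb, 1.5 kb/s per leg by default), and records at sampling
times the loop set, the count of cohesins still bridging their anchor
pairs, and cumulative translocation.

**Gap-closure capacity.** With a single species loaded at once and no
unloading, inter-condensin spacings are near-exponential and each gap
closes at twice the leg speed, so the uncovered fraction decays as
exp(−2vt/µ). Reaching the dense, rod-forming array (98% coverage — "most
gaps closed") therefore costs each condensin ln(1/0.02) ≈ 3.9 mean loop
lengths of extrusion; the experiment (`required_processivity_ratio`)
measures 2v·t* at the first crossing of 98% coverage, divided by the
saturated-array mean loop, and yields 3.9–4.5 on a 40 Mb lattice. The
lattice is 40 Mb because the asymptotic exponential-gap argument needs
~100 gaps; at 10 Mb (~25 gaps) the single largest gap dominates and the
measured ratio drops to ~3.2.

## Coarse-grained chromatid builders

Beads are 10 kb (10⁴ beads per 100 Mb chromatid). A bead's effective
diameter follows from the volume density φ: d = (6·(bead Mb)/(π·φ))^{1/3},
76 nm at 44 Mb/µm³. Construction is direct — anchored random walks for the
condensin scaffold, Gaussian bridges for loop interiors, geometric
confinement, and a local density cap — rather than Brownian dynamics;
thermal averaging is approximated by averaging observables over replicate
seeds. Loop arrays fed to the builders are either extrusion-engine frames
or exponential size mixtures (what stochastic loading produces), tiling
the genome at full coverage or interleaved with bare-fiber linkers at
partial coverage.

**Cylinder geometry.** The axial length is L = (genome Mb)/ρ and the
radius R follows from mass conservation, πR²L·φ = genome. For the
condensin II best fit (ρ = 42.5 Mb/µm from 17 Mb per 400 nm of pitch,
φ = 44 Mb/µm³), a 100 Mb chromatid is 2.35 µm long with R = 0.55 µm.

**Scaffold.** Loop-anchor beads perform a fixed-step random walk (step =
gap size g) attracted to a guide curve; the attraction weight (0.6) leaves
the scaffold loosely, not rigidly, following the guide. The guide for the
helical mode winds 2π per turn length T at 45% of the cylinder radius,
with correlated axial (σ = 60 nm) and angular (σ = 0.2 rad) jitter of 3 Mb
correlation length — an irregular, not crystalline, helix — and its ends
map to opposite cylinder caps. The scaffold-radius fraction and jitter
levels are construction constants fixed once against the qualitative
target they control (a strong second diagonal, a weak third, scaffold
confined well inside half the radius); they are deliberately coarse knobs,
not fitted parameters.

**Loop interiors.** Each loop of n beads is a Gaussian bridge between its
anchors with per-step width chosen so the loop fills the space available:
in cylinder modes, width ∝ R/√n (every loop can reach the surface — this
is what lets loops one and two gyres apart touch and produce the third
diagonal); in the unconfined brush mode, width = (3/√2)·r_b/√n where r_b
is the brush radius from the volume-density closure
πr_b²·φ = (loop Mb)/(gap µm). The 3/√2 factor makes the bead-averaged
transverse spread match the uniform-disc-equivalent radius exactly, so the
realized brush-tube density equals φ. Cylinder modes additionally fold
escaping beads back through the wall and re-jitter beads in grid cells
above 3× the target density (a light excluded-volume surrogate; it is not
applied in the unconfined mode, where crowding above target density cannot
arise and the jitter would dilute the brush tube).

**Stretched random-walk mode (condensin I).** The backbone is a worm-like
walk of anchors (step = g = 20 nm) whose natural persistence equals the
brush radius (144 nm for the best fit) — the standard result that a
bottlebrush is stiff on the scale of its own thickness. The end-to-end
extension is imposed by reallocating only the longitudinal component (a
per-chain constant drift along the stretch axis); transverse fluctuations
stay free. Bridging all three components was tried and rejected: pinning
the transverse displacement at the chain ends systematically distorts
contact statistics at 20–40 Mb. With the best-fit 4 µm extension for
100 Mb, the backbone is diffusive (MSD linear in genomic distance) across
2–8 Mb and the ensemble log-derivative of P(s) averages −1.5 there, the
random-walk signature. Ensembles of ≥40 replicates are used when this
slope is measured: the free transverse wander makes single chromatids
vary, and the ensemble mean has a seed-to-seed spread of ~0.07 at 40
replicates.

**Sister pairs.** In bypass mode each sister gets its own axis (1.6 R
apart) and the bead nearest each cohesive-link locus is pinned near the
midplane — links are inside loops, distal from the scaffolds. In stall
mode, loop arrays are truncated at link positions (condensins cannot pass
them), both sisters share one axis, and links sit at loop bases on it.
Cross-section line scans (histograms of the transverse offset, unit area,
peak and FWHM reported) then show the discriminating geometry: two
separated condensin peaks with central cohesin (bypass) versus coincident
condensin/cohesin peaks (stall).

**Nested model.** Condensin I loops subdivide each condensin II loop; the
outer anchors follow the helical scaffold, the inner-anchor chain bridges
between consecutive outer anchors across the outer loop's territory, and
inner loops decorate it at the condensin I brush radius.

## Contact analysis

Contacts are bead pairs within a capture radius of 2 bead diameters
(~150 nm at 44 Mb/µm³). P(s) from conformations is a true contact
probability: pair counts per log-spaced separation bin divided by the
number of bead pairs at that separation; 10 bins/decade by default, finer
(25–35) where band detection or derivative estimation needs it. P(s) from
a binned map averages each diagonal. The two routes agree up to binning
error (asserted in tests).

The log-derivative is computed on the raw log-log curve and then smoothed
(Gaussian, σ = 1 bin in log s, edge mode "nearest"), so exact power laws
keep their slope to the boundary.

**Loop size.** Inside a loop array the decay of P(s) is shallow; past the
loop scale it steepens beyond the random-walk exponent. The estimator
finds the first downward crossing of slope −1.5 that follows a shallow
(> −1.2) stretch and divides its position by a calibration constant of
1.88, determined once on simulated arrays of known mean loop size
(100–800 kb exponential mixtures at 60% coverage, 8 replicates of 50 Mb)
and frozen; recovery is within ±25% across that range. The mean loop size
sits left of the feature mostly because an exponential mixture's typical
loop is smaller than its mean. Loop-free chromatin (slope at or below
−1.5 throughout) yields no estimate, with a warning.

**Periodic diagonals.** log₁₀P is smoothed (σ = 1.5 bins), detrended with
an iteratively reweighted polynomial baseline (degree 3, points above the
baseline down-weighted so bumps cannot drag it up), and peaks above a
prominence of 0.02 (log₁₀ units) are kept; positions are half-prominence
centroids in log s. The default search window starts at 6 Mb — below that
the loop-regime curvature of these models produces baseline artifacts —
and ends at 80% of the chromosome. The dip depth between the main and
second diagonal is the first peak's detrended height over the minimum
before it. For contact-starved curves (a stretched brush at tens of Mb) a
single ensemble can carry lumpy chain-to-chain fluctuations that mimic
weak bands; `matched_diagonals` therefore accepts only bands that
reproduce at the same position (±0.06 decades, prominence ≥ 0.1) in two
independent ensembles. The helical model's bands pass this filter; the
stretched-brush model's do not.

**Feature scores.** Observed/expected uses the per-map mean at each
separation. Compartment strength is distance-stratified: the within-type
over between-type mean O/E ratio per separation, pair-count weighted —
pooling across separations first would confound compartment identity with
distance. Dot strength is a pileup: the central-bin O/E over the mean of
the outer 3-bin ring of a ±10-bin window (±6 bins at 25 kb for the
short-range fixture dots), averaged over dots; dots closer to the diagonal
than the window are skipped and counted. Both scores are ~1 under label or
position shuffles and recover planted folds, and are reported normalized
to a supplied G2 reference when given.

**1D-to-map bridge.** To score how collision scenarios erode dots, loop
trajectories are converted to maps by planting dot enrichments at the
anchor pairs cohesins still bridge, on a Poisson-sampled s⁻¹ background
(the fractal-globule exponent of G2 chromatin). This bridge is a modeled
shortcut — it assumes dots vanish exactly when their cohesin leaves the
anchors — and is used only for scenario comparison, where that assumption
is the point.

## Model fitting

Grid search, because every evaluation is a stochastic simulation. The
objective is the RMS of log₁₀(model/target) over the fit range
(30 kb – 60 Mb by default), interpolating the model curve in log-log;
bins at or below a background floor (10⁻⁶ of the curve maximum unless a
measured inter-chromosomal level is supplied) are masked. Each grid point
is scored per replicate, and the mean and SEM are reported; the surface is
flagged degenerate when its spread is within noise (2× median SEM) or
small relative to a uniformly poor fit level (< 10% of the minimum).
Closed-loop tests recover generating parameters within one grid step for
both chromatid modes on noisy targets (lognormal noise, CV 0.05).

## Speed estimators

All estimators convert minutes to seconds in one place and report kb/s;
printed values are rounded to two significant figures, raw values
retained. The increment estimator flags concave (saturating) series as
lower bounds. The gap-closure estimator's multiple defaults to 4.5
(range 4–5, per the capacity theory above). The area→volume conversion
uses the isotropic exponent 3/2, so a 2-fold projected-area compaction is
reported as 2.83-fold in volume — "approximately 3-fold" by rounding,
documented rather than hidden. Because the activation time after release
from a G2 block is not knowable exactly, the estimators take explicit
time points rather than asserting an offset. Applied to engine
trajectories, the estimators recover the configured total extrusion speed
(twice the per-leg speed) within 20% before saturation.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analysis assumes:
CTCF sites with exponential spacing and random orientations, dots only at
convergent pairs, cohesins parked there; exponential loop-size mixtures;
geometric A/B blocks near 50/50; Poisson cohesive links; power-law maps
with planted, known enrichments; simulated P(s) targets with
multiplicative lognormal noise. They do not emulate read-level Hi-C
(no coverage bias, no balancing artifacts), sequence context, replication
timing, centromeres/kinetochores, or anaphase. Passing tests therefore
show that the estimators and detectors are correct and calibrated on data
obeying their own assumptions — not that those assumptions hold in any
particular experimental dataset.

## Problem sizes and determinism

Default study scale: one 100 Mb chromosome; 3D ensembles of 20–40
replicates at 10 kb/bead; extrusion runs of 10–40 Mb at 1 kb/site; grids
of a few dozen points at 40 Mb with 4–6 replicates. These sizes were
chosen so the whole pipeline (including the test suite and the acceptance
script) reruns from scratch in minutes on one CPU while keeping every
headline statistic stable to a few percent across seeds. Every stochastic
routine takes an explicit seed; ensembles are derived seed sequences, and
identical seeds give bit-identical results.

## Known limitations

* Constructive conformations approximate a Brownian-dynamics ensemble;
  excluded volume is a cap-and-jitter surrogate, so knot/catenation
  statistics and entanglement effects are out of reach.
* The helix jitter, scaffold-radius fraction and loop-width factor are
  coarse constants, fixed once; the prominence (though not the position)
  of the periodic diagonals depends on them.
* The condensin I mode's contact statistics beyond ~20 Mb are dominated by
  rare fold-backs of a taut chain and should only be interpreted through
  the reproducibility filter.
* The 1D engine has no chemical ATPase cycle, force-dependent speeds, or
  diffusion of passively bound complexes; "pushing" moves obstacle chains
  rigidly one site at a time.
* Cohesive-link placement density along arms (default 1/Mb, configurable)
  is a synthetic choice; sister-pair geometry is constructed, with links
  as positional pins rather than dynamic tethers.
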