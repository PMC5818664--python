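# Methods

## The system being modelled

A computational-electrophysiology setup stacks two membranes, each
carrying one channel copy, in a periodic box.  The axial slab between the
membrane midplanes is compartment (a), the complementary periodic slab is
compartment (b).  Holding compartment (a) at a small surplus of permeant
cations (Δn = 2 by default) sustains opposite-sign transmembrane voltages
across the two membranes, and permeation events can be counted directly.
`permeon` implements the analysis layer of such runs: it never integrates
equations of motion, it measures trajectories.

All lengths are Å, times ps, charges elementary units, energies kJ/mol,
potentials mV.  Coordinates are wrapped into [0, box) once at ingest; all
axial intervals are half-open `[lo, hi)` so boundary frames have a unique
label.

## Channel frame and regions

Each channel copy has a unit axis (membrane normal, +s extracellular), an
origin, and contiguous axial intervals for intracellular bulk
[−41, −15), cavity [−15, −5), SF [−5, 5), vestibule [5, 12) and
extracellular bulk [12, 41) in the channel-local coordinate
`s = (x − origin)·axis`.  Radially, the SF/vestibule levels split into
the pore core (r ≤ 4.5 Å), the side-portal band (4.5 < r ≤ 10 Å) and
membrane; the cavity level uses an 8 Å radius.  None of these extents is
dictated by experiment — they are engineering defaults and every one is
config-overridable (`data/default_geometry.yaml`).  In the default
double-membrane layout (box 40×40×160 Å, midplanes z = 40 and 120, the
upper copy pointing −z) both copies face compartment (a) with their
extracellular side; arbitrary points are attributed to the copy with the
smaller |s|, which partitions the periodic box cleanly.

Filter sites: B34 and B23 are the T63 and V64 carbonyl planes
(s = −1.2, +1.0); S4/S3/S2/S1 are the adjacent cage midpoints.  Whether
"B" sites denote in-plane or between-plane positions is a convention; the
in-plane choice is recorded here, not asserted as anyone's intent.  The
off-axis S_side site is described per subunit by atom selectors: the D66
and F69 backbone carbonyl O plus the side-chain O of either S70 (same
subunit) or D66 (spatially neighbouring subunit).

## Synthetic trajectories

The generator is a kinetic-hopping model, not dynamics.  Ions rest at
jittered bulk anchors (Gaussian jitter, default σ = 0.3 Å, which makes
classification-robustness tests meaningful); complete crossings arrive as
a Poisson process at per-species rates (defaults 1.8 inward / 1.9 outward
per μs for K⁺, the event rates of the permeation runs the package was
built around).  A crossing follows the scripted waypoint sequence
bulk → (vestibule | side portal, per `side_entry_fraction`) → SF →
cavity → opposite bulk, with ~300 ps waypoint dwells and an exponential
SF dwell (mean 0.5 ns — a placeholder motivated only by "short-lived"
filter residence; no measured distribution exists).  Distractor
excursions enter the SF and return to the same side.  Each event is
assigned to an idle ion of the right species in the origin compartment;
unassignable events are dropped and never enter the ground-truth sidecar,
so recovery tests compare against exactly what was planted.

Hydration shells are rigid: each cation carries `hydration_waters`
dedicated waters at fixed 2.4 Å offsets, frozen in place while the ion
is inside the SF when `shed_shell_in_sf` is set.  Carbonyl pseudo-atoms
(C, O) for T62/T63/V64/G65 are emitted per subunit and channel copy, the
crystal C=O pointing at the pore axis; during scheduled flip intervals
the T62 O swings to the far side (~180°) and the T63/V64 carbonyls of
that subunit shift outward by `flip_widen` (1 Å), emulating the
asymmetric filter deformation that accompanies the flip.  Subunits sit at
azimuths A = 0°, B = 180°, C = 90°, D = 270°, so the default pairing
convention ((A,B), (C,D)) measures geometrically opposing carbonyls; the
diagonal pairing is available by argument.

What the generator does *not* emulate: force-field energetics, water
dynamics, knock-on correlations between ions, realistic dwell-time
distributions, or MD kinetics of any kind.  Passing recovery tests shows
the analysis code is correct against its own contracts — it does not
show that real trajectories are this clean, and hysteresis/cutoff
defaults may need retuning on MD data.

## Event counting

`full_crossing` run-length-encodes each ion's region-label sequence,
drops visits shorter than the hysteresis dwell (default 100 ps,
configurable; boundary flicker otherwise splits crossings), and walks a
bulk→SF→opposite-bulk state machine.  Same-side excursions never count.
`coupled_exchange` implements the literal coupled rule: an SF entry from
one side matched with a different ion's SF exit to the other side within
a window (default ±1 frame; the original rule names no window, so it is
exposed as config).  Direction follows the origin side (extracellular →
inward).  Channel attribution comes from the SF frames traversed.

Pathway: an event is a side entry when its transit carries the
SIDE_PORTAL label, or when the ion sits within a first-shell cutoff
(Na⁺–O 3.2 Å, K⁺–O 3.6 Å — typical first-shell distances, not measured
here) of any S_side selector set during the frames bracketing SF
entry/exit.

Conductance `G = n·e/(t·|V|)` is reported in pS (n events, t in μs, V in
mV), current `I = n·e/t` in pA.

## Electrostatics

The laterally averaged charge density is binned over z (time-averaged;
the sum of ρ·slab volume reproduces the total charge exactly).  The
potential solves `φ'' = −ρ/ε₀` with φ = 0 and φ' = 0 at a declared
reference (default: the left box edge — the original prescription names
no reference, so it must be explicit).  The binned ρ is treated as
piecewise constant, for which the double integral is a closed-form
per-bin quadratic: the solver adds no quadrature error beyond the
binning, which is why agreement with an independent ODE solve at 1e-6
relative is a meaningful test.  Vacuum permittivity only — the method is
the bare double integration of the simulated charge distribution, with
no dielectric profile.  Per-membrane ΔV is the difference of plateau
means over the central 50 % of each bulk compartment (away from
interfacial oscillations; window fractions configurable).

## Densities and PMF

Occupancy is histogrammed over (s, r) in the owning copy's channel
frame.  Boltzmann inversion uses `w = −k_B T ln(p/p_ref)` at T = 300 K
with p_ref the maximum-density bin, so the minimum of w is zero and
barriers are positive; zero-count bins are masked, never imputed.
Hydration numbers count water oxygens within first-RDF-minimum cutoffs
(Na⁺ 3.1 Å, K⁺ 3.5 Å); coordination states pair the count of engaged
S_side protein oxygens with the water count, and record which selectors
contributed.

## Conformer diagnostics

A carbonyl is `crystal` when its C=O vector lies within 60° of the
crystal reference direction (pointing at the pore axis), `flipped_T62`
beyond 120°, `other` between; runs shorter than a temporal hysteresis
(3 frames) merge into the preceding stable label.  The thresholds are a
classification convention around a ~180° flip, not measured quantities.
d1/d2 are distances between opposing T63/V64 carbonyl *oxygens* (the
deformation of interest is of the carbonyl-lined pore, not of Cα
positions).

H-bonds use H···O ≤ 2.5 Å and N–H···O ≥ 150°, skipping covalently
adjacent residues; when a structure carries no protons the amide H is
rebuilt at 1 Å from N along the bisector of the N–CA and N–C(prev)
bonds.  Amide contact maps list same-subunit H–H pairs under a cutoff
(default 4 Å): the geometric stand-in for NHHN cross-peaks, with no
claim that presence/absence predicts intensity.

The idealized filter scaffolds (residues 59–70, four chains) are
geometric constructions, not energy-minimized structures: the crystal
scaffold satisfies all vicinal amide H–H contacts in L61–G65 plus the
T63NH–T60CO and V64NH–V59CO bonds; the flipped scaffold opens the
T62–T63 amide pair to exactly 4.5 Å, breaks those two bonds and forms
V64NH–T62CO.  `widen` shifts the T63/V64 carbonyls radially so opposing
O–O separations grow by exactly the requested amount.

## Numerical and design choices

* Determinism: every stochastic routine takes a seed; identical seeds
  give bitwise-identical trajectories and byte-identical pipeline
  summaries (floats rounded to 6 digits in JSON).
* `maintain_imbalance` picks the surplus-compartment ion and
  deficit-compartment water closest to their bulk centres (axial periodic
  distance), ties broken by lowest id — the original maintenance
  algorithm's selection rule is not public, so a deterministic substitute
  is documented instead.  A swap changes Δn by exactly 2; odd targets
  raise a parity error.
* Degenerate inputs: empty trajectories yield empty event lists; an
  all-zero histogram, a non-uniform grid, equal midplanes, or gapped
  region intervals raise typed errors.
* Problem sizes: recovery analyses run on ~2 μs of synthetic time at
  100 ps frames with a few dozen ions (tens of thousands of frames,
  ~150 particles) — ample statistics for exact-recovery and binomial
  checks at interactive runtimes; the statistical tolerances (3 binomial
  SE, PMF RMSE over the well core) are set by the sampling sizes, not
  tuned.

## Known limitations

Absolute event counts of microsecond atomistic MD are out of reach by
construction — the generator reproduces bookkeeping structure, not
kinetics.  The PMF carries no error bars (block averaging is future
work).  The Poisson solver ignores periodic-image corrections and
dielectric screening, matching the plain double-integration
prescription.  The columnar text trajectory format is the only ingest
contract; binary MD formats would be an optional extra.
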