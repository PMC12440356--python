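# Methods

`thymosim` simulates early T-cell development in a slice of the embryonic
medaka thymus as a hybrid agent-based / continuum model. This note documents
the model, its assumptions, the calibration constants, and what the synthetic
scenarios do and do not show about real tissue.

## Spatial representation

The simulated domain is a 5-µm-deep slice of the lower half of the radially
symmetric organ (about one tenth of the embryonic thymus volume), a half-disc
of radius 46 µm. Because cell radii (2.5 µm) equal the half-depth, dynamics
are effectively planar: all cell centres sit on the mid-plane, and the
confinement in z is implicit. The outer arc is the ventral organ surface —
progenitors enter through it and naive T cells leave through it; the chord is
the organ midline and acts as a reflecting wall.

Thymic epithelial cells (TECs) are static agents: a body sphere of radius
r_TEC plus `n_protrusions` chains of three tangent spheres of radius
0.5·r_TEC radiating in-plane, clipped at the domain boundary. Bodies are
placed on `n_subdivisions` concentric arcs at radii k/(n+1)·R, spaced
2.6·r_TEC apart along each arc with small angular jitter. More subdivisions
means more arcs, hence more TECs (the density axis of the architecture
scan). The spacing constant was calibrated so that at the reference
architecture and homeostatic population, TECs occupy ≈44% and thymocytes
≈56% of the combined cell volume (Monte-Carlo union-of-spheres estimate).
All TECs present the Notch ligand Dll4. In the reference (`cortical_subset`)
expression mode, every other TEC in the outer half-annulus secretes IL-7
(an evenly interleaved half), producing a patchy, short-ranged cortical
cytokine field; `all_tecs` and `none` override this uniformly. The
patchiness is a deliberate design choice: with spatially uniform cortical
secretion the clone-size distribution becomes bimodal (clones either never
divide or divide maximally), whereas discrete IL-7 "islands" with finite
carrying capacity reproduce the observed broad, mid-heavy distribution of
clone sizes. The interleaving is deterministic rather than a random subset
so that the source count — to which the homeostatic population is highly
sensitive — does not vary binomially between replicates.

## Extracellular IL-7

The extracellular concentration obeys

    ∂c/∂t = D ∇²c − k c + Σᵢ sᵢ − sinks

solved by explicit finite differences on a 2.5-µm voxel grid (two z-planes)
masked to the organ, with no-flux boundaries and automatic sub-stepping
below the stability bound h²/6D; decay is integrated exactly per sub-step
(operator splitting), and the mass budget (sources − decay − sinks) closes
to better than 1e-6 relative per step. Every voxel intersecting a secreting
TEC sphere is a source of strength s_i. Defaults D = 1 µm²/s, k = 0.08 s⁻¹
give a decay length √(D/k) ≈ 3.5 µm — a gradient confined to roughly one
cell diameter around each source, the "short-ranged cortical gradient"
regime. s_i = 2.9e-4 a.u./s sets the near-source concentration at the scale
of the normalization constant c* (below).

Without depletion, thymocytes do not touch the field. With the depletion
flag, each thymocyte removes ligand over its voxels at a rate proportional
to its signal-transduction activation (receptor level × local mean
concentration × activation rate); dominant-active clones remove at the
constant rate of their receptor level. A conversion constant
(`depletion_efficiency` = 0.1) bridges the arbitrary signaling scale and the
concentration scale; it was fixed so that depletion at reference rates
perturbs the mean extracellular IL-7 only mildly, the regime the biology
indicates. Sinks are clamped per sub-step to the available voxel mass
(counted), keeping the field nonnegative.

## Signal transduction

Each thymocyte carries a constant receptor level [IL7R] drawn uniformly on
[0, 1] at immigration and inherited clonally. IL-7 pathway activity follows

    dσ/dt = [IL7R]·⟨c⟩·a − d·σ        (wild type)
    dσ/dt = [IL7R] − d·σ              (dominant-active receptor)

with a = 240 hr⁻¹ and d = 50 hr⁻¹ at reference, integrated exactly per
15-s step (linear ODE, piecewise-constant drive — unconditionally stable).
Notch activity rises toward 1 at 1.0 hr⁻¹ while the cell's surface is
within 0.5 µm of any TEC sphere and decays at 2.5 hr⁻¹ otherwise;
dominant-active Notch is pinned at 1.

For the proliferation gate, both activities are normalized to their
wild-type maxima and summed. The IL-7 normalization is the steady state of a
receptor-saturated cell at the reference peak cortical concentration under
reference rates: σ_max = c*·a_ref/d_ref with c* = 1/240. This scale makes a
dominant-active clone (σ* = [IL7R]/d = 1/50) exactly equivalent to the best
wild-type cell parked at peak IL-7 — the defining property of that lesion —
and caps each normalized activity at 1, so receptor overexpression saturates
the IL-7 term and becomes insensitive to IL-7-parameter changes. The
normalization is a fixed model constant: scan scenarios that raise a or
lower d genuinely raise the normalized signal up to the cap.

## Cell cycle, differentiation, selection

Cycle durations are Erlang with fixed shape k = 50 and scanned mean µ
(reference 7 hr → SD ≈ 0.99 hr; the fixed shape makes SD scale as µ/√50 for
other means). The cycle splits into G1 (half the drawn duration) and
S/G2/M. During G1 the combined normalized signal is polled every step
against the threshold θ = 1.4 (≥ convention); reaching it latches
commitment, and the cell divides when the drawn duration elapses. A cell
whose G1 ends without commitment waits in extended G1 and can commit later,
completing S/G2/M afterwards. Daughters are placed beside the mother at full
reference volume (no volume halving, no density-dependent proliferation
feedback — crowding acts only through volume exclusion), inherit clone id,
receptor level, lesion flags and developmental clocks, and draw fresh cycle
durations.

Developmental progression runs in parallel: a commitment (proliferative)
phase whose progress rate is (0.25 + 0.75·σ_Notch)/T_diff — completing in
exactly T_diff = 24 hr under saturating Notch, up to 4-fold slower without
(a strict mode with rate ∝ σ_Notch, never completing at zero Notch, is
available but off by default) — then a fixed 24-hr differentiation phase
during which cycle entry is closed but already-committed cells finish their
division. Differentiation ends in probabilistic selection (p = 0.73
positive): positively selected cells mature for a 14-hr dwell, then drift
radially outward and exit through the ventral arc; the rest shrink at
1 µm/hr and are removed below 1 µm radius. At selection each cell is also
assigned one of two T-cell sublineages (p = 0.5, bookkeeping only — no
behavioral difference downstream). The 14-hr post-selection dwell resolves
the open design choice between purely geometric exit and a timed exit as
timer-then-geometric; it was calibrated (with the Notch rates) so the median
entry-to-exit transit of non-dividing lineages is about three days.

## Mechanics and motility

Cells are overdamped soft spheres: linear-spring repulsion under overlap and
a weak linear adhesion (0.25 of the repulsive stiffness) out to 1.2× the
contact distance, with displacement per step equal to 0.2× the overlap
(mobility folded into the constant; a lone overlapping pair relaxes in ~5
steps). TEC spheres exert the same forces but never move. Displacements are
capped at one cell radius (runaway-overlap protection, logged). Walls
project cells back into the slice; exit-bound cells ignore the outer wall.
Active motility is a persistent random walk: ETPs move at 4 µm/min with
heading noise 0.6 rad/√min, maturing thymocytes at 2 µm/min with noise
1.2 rad/√min; the slow-speed lesion halves speed. Apoptotic cells stop
moving actively.

## Clonal bookkeeping and lesions

Every immigrant founds a clone labelled by its own cell id; the label is
inherited at division. The lineage forest records per cell: parent, birth
and end times, and end cause (divided / died / exited / alive at end).
Clone size is the number of terminal leaves regardless of fate; rounds of
division is log2 of the mean clone size (per-clone log2 values are also
reported for distribution statistics). In lesion scenarios, the first
immigrant after t = 60 hr (homeostasis) carries the configured lesion set;
exactly one lesioned clone exists per run. Lesions compose: wild-type-max
receptor, dominant-active receptor (ligand-independent signaling and the
constant-rate field sink), 10× receptor overexpression, autocrine IL-7
secretion over the cell's own voxels, pinned Notch, halved differentiation
rate (doubling the proliferative window), and halved speed.

## Update order and reproducibility

Each 15-s step applies, in a fixed documented order: diffusion sub-steps →
signaling updates → fate (gate, cycle, division, differentiation,
selection) → mechanics and motility → immigration and departures → logging.
A single PCG64 generator seeded from the run seed drives all randomness in
a fixed consumption order, so identical (params, seed) reproduce bit-equal
event logs and fields. Scan entries derive distinct seeds by a counter
scheme, (base·1000003 + index) mod 2³¹, injective over any realistic scan.

## Calibration and frozen constants

Only the reference configuration was used for calibration; all constants
were then frozen for every scan scenario and lesion screen. Anchors:
homeostatic population ≈ 98 (time-average over t ≥ 60 hr), ≈3-day
entry-to-exit transit, thymocyte/TEC volume shares ≈ 56/44%, a broad
clone-size distribution averaging ≈1 round of division with a small tail of
4-round clones, and a no-proliferation floor (no IL-7) of ≈42 cells. The
resulting constants: homing interval 1.5 hr, exit dwell 14 hr, p_select
0.73, Notch on/off 1.0/2.5 hr⁻¹, field constants as above, TEC arc spacing
2.6·r_TEC, cortical secreting fraction 0.5. The anchors are not all exactly
attainable at once: the frozen configuration realizes replicate-mean
populations of roughly 105±16, floors of ≈44, shares of ≈57/43 and transits
of ≈67 hr, while the pooled per-clone rounds of division settle around
0.7–0.8 — raising the division rate toward a per-clone mean of 1 inflates
the homeostatic population well past 98 unless immigration is slowed, which
in turn breaks the no-IL-7 floor. The population anchors were given
priority.

With those constants frozen, the architecture and IL-7-signaling scans
reproduce every monotone ordering of the published screens: population
rises with TEC size/protrusions/density and with the activation rate, falls
with the deactivation rate and with lost IL-7 expression; sparse-TEC or
IL-7-free niches collapse proliferation to the immigration-residence floor;
clonal turnover is longer in sparse niches than dense ones; dominant-active
and overexpressing IL7R clones expand ≈4 rounds against ≈1 round for
wild-type clones, and their signaling is provably insensitive to IL-7
parameters. Absolute populations in the strongest-IL-7 scenarios
(ubiquitous TEC expression; high activation with low deactivation) overshoot
the published means: the capped additive gate used here has a harder dose
response than the original implementation, whose exact form we did not
attempt to reverse-engineer. These readouts should be interpreted via
orderings, not absolute counts.

## Problem sizes

A full run is 48,000 steps of 15 s (200 simulated hours, ≈8.3 days) with
~100–450 agents and a 37×19×2 voxel field, completing in well under a
minute on one CPU. The test suite and the acceptance script use full-length
runs with small replicate counts (2–5 seeds per readout), which the
between-replicate clonal-wave variability makes the dominant source of
uncertainty (single-run homeostatic means scatter by roughly ±20 cells).

## Known limitations

TECs are static (no niche remodeling, no TEC proliferation); there is no
cross-regulation between IL-7 and Notch pathways, no feedback from
proliferation onto differentiation, and no organ growth; selection is
fate-only (no T-cell receptor clonotypes); z-dynamics are degenerate by
construction of the slice; and the synthetic scenarios inherit all of these
simplifications — agreement with them shows the mechanisms are sufficient
to generate the published population/clonal patterns, not that parameter
values transfer to real tissue.
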