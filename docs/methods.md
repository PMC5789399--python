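# Methods

## Scope and model

The package analyses wound self-sealing of succulent leaves as a
combination of three measurement layers — kinematic (bending angles from
tracked points), mechanical (tensile stress–strain of leaves and tissue
layers) and cellular (turgor-based tissue stiffness) — tied together by a
rank-based repeated-measures inference over the humidity × time design.
All angles are in degrees, stresses and moduli in Pa (MPa at the tissue
scale), lengths in metres for tensile work and micrometres for anatomy.

## Bending-angle kinematics

Angles are *line* angles taken mod 180° and reported in (−90°, 90°]: the
tracked base and tip lines are undirected, and with this convention the
actual bending angle δ = β − α and the relative bending angle
γₙ = δₙ − δ₀ are exactly invariant under rigid motion and uniform scaling
of the whole configuration (property-tested to 1e−9 deg).  The price of
the mod-180 convention is aliasing: a true inter-frame bending jump of
90° or more is indistinguishable from a small one.  A continuity guard
therefore rejects any frame-to-frame step of the wrapped bending angle at
or above 45° — half the ambiguity bound and far above physiological rates
at 30-s frame intervals.  Observed sealing movements are tens of degrees
over tens of minutes, so the guard only trips on corrupted tracks.

Coordinates may be in pixels or millimetres (angles are scale-free).  A
`y_down` flag accommodates image-convention exports by mirroring before
angle computation, preserving the sign convention "closure is positive".
Evaluation-time sampling takes the nearest frame, ties toward the earlier
frame, and refuses times farther than half a frame interval from any
frame.  The sampling rule is a package choice; the convention is
documented rather than inherited, since tracking tools leave it open.

## Tensile analysis

Engineering stress and strain are used throughout (consistent with the
small strains of the linear range).  Whole-leaf cross-sections are
ellipses measured at five stations; the epidermis uses a rectangle mode;
tapered vascular strands use a circle from the basal radius.

The elastic modulus is the least-squares slope over the **longest window
anchored at zero strain whose linear fit reaches R² ≥ threshold**.  The
scan is deterministic and auditable: every prefix window of ≥ 10 points
is fitted, and the longest passing one wins.  The default threshold of
0.999 suits records with laboratory force noise; it is a *noise-scaled*
parameter.  For noiseless (synthetic) records a threshold this loose lets
the window creep past the yield point — the accumulated curvature needed
to push R² below 0.999 grows with the already-fitted linear run — which
biases the slope by roughly 1% regardless of sampling density.  Recovery
tests on noiseless data therefore run the same scan with R² ≥ 1 − 1e−7,
which recovers the generator's modulus to better than 0.1%.  If no window
passes, the error suggests relaxing the threshold instead of silently
fitting a shorter region.

Poisson's ratio is computed between the first and last image of the
linear-elastic range: ν = (Δd/d₀)/(ΔL/L₀), with Δd the transverse
contraction.

## Turgor-based tissue modulus

The parenchyma/chlorenchyma modulus is modelled as affine in turgor with
a separable geometry term:

    E_tissue = [3 P + 2 (t_cw / d_c) E_cw] / (1 − ν)

The structure — a turgor term linear in P plus a wall term proportional
to the wall-thickness fraction times the wall modulus — follows
thin-walled pressurised-cell mechanics: deforming the aggregate does work
against cell pressure and against wall stretching, and the (1 − ν)⁻¹
factor amplifies both through transverse coupling.  The two dimensionless
coefficients (3 and 2) are calibrated against reported
parenchyma/chlorenchyma measurements: at the median parameters
(P = 0.042 MPa, d_c = 77 µm, t_cw = 0.42 µm, ν = 0.28, E_cw = 5.00 MPa)
the relation gives 0.251 → 0.25 MPa, and across the measured turgor range
0.03–0.09 MPa it spans 0.20–0.43 MPa, matching the reported spread.  The
function exposes its two-term decomposition so the turgor and geometry
contributions can be reported separately; affinity in P and monotonicity
in t_cw/d_c and E_cw are contractual and property-tested.

Supporting conversions: the ring-equivalent thickness of a net of
peripheral vascular bundles is Σ areas / (2πr) at the middle radius r
(the annulus of equal total cross-section); thin-section shrinkage of
succulent parenchymatous tissue (~15% of linear dimension) is undone by
dividing by (1 − shrink fraction) — shrinkage is treated as linear, not
areal, and the fraction is configurable; absolute humidity is
rh × saturation density, with the saturation density either supplied
directly (to reproduce published values exactly) or computed from air
temperature via the Magnus approximation (Alduchov–Eskridge constants
A = 610.94 Pa, B = 17.625, C = 243.04 °C) and the ideal-gas law.  At
22 °C this gives 19.37 g/m³, matching the published 19.41 g/m³ saturation
value to within 0.3%; note that value corresponds to ≈22 °C rather than
the reported mean air temperature of 22.95 °C, which is why a
user-supplied saturation content is the default route for reproducing
published conversions.

## Rank-based repeated-measures inference

The design is fully within-subject: each leaf contributes one γ value per
condition × time cell (4 × 6).  The response is pooled-rank transformed —
all values ranked together, average ranks for ties — and the classical
two-factor within-subject ANOVA partition is applied to the ranks.  Error
terms are the effect-by-subject interactions, giving df (a−1), (a−1)(n−1)
for main effects and (a−1)(b−1), (a−1)(b−1)(n−1) for the interaction —
(3, 48), (5, 80), (15, 240) at n = 17.  Pooled ranking over the whole
grid is the package default (`rank_mode="global"`); running on raw values
is available via `rank=False`.

Sphericity is assessed per effect from the covariance of
orthonormal-contrast scores (Kronecker products of the factor contrasts
for the interaction): Mauchly's W with the chi-square approximation
including the second-order Box term — the convention of R's
`mauchly.test` — and the Greenhouse–Geisser ε = tr(S)²/(d·tr(S²)),
clamped to [1/d, 1].  Both the uncorrected and ε-corrected p-values are
reported.  At n = 17 the interaction contrast space (15 dimensions) is
just below the subject count, so its W is extremely small but defined;
designs with n − 1 below the contrast dimension yield a singular
covariance and a degenerate W = 0 with p = 0, reported rather than
hidden.

Post-hoc comparisons are paired Student t-tests on subject means
marginalised over the other factor, on the rank scale by default (the
scale of the omnibus test), with Bonferroni adjustment
p_adj = min(1, m·p), m = k(k−1)/2.  Whether the original analyses paired
on raw or rank scale is not documented; the choice here is explicit and
switchable.

Supporting tests pin conventions explicitly: Spearman's ρ is Pearson on
average ranks with an exact permutation p for n ≤ 9; the
Wilcoxon–Mann–Whitney statistic is the U of the first sample (the
`wilcox.test` W convention), with exact enumeration for n₁+n₂ ≤ 12 and a
tie-corrected, continuity-corrected normal approximation otherwise;
quartiles use linear interpolation between closest ranks.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions the test suite runs under.

**Sealing tracks.**  The latent relative bending angle follows a
saturating exponential γ(t) = (γ∞ + u_s)(1 − e^(−t/τ)) — the simplest
two-parameter law with the observed behaviour (monotone rise to a
condition-dependent asymptote).  The default four conditions use
γ∞ = 18°, 10°, 2°, −12° and τ = 8, 12, 20, 6 min for 24%, 49%, 100% r.h.
and the water droplet: asymptotes fall with humidity and are negative for
the droplet, with faster kinetics where the humidity gradient is steeper.
These are plausible shapes chosen once for the simulator, not published
measurements, and no test compares them to published sealing curves.  The
subject effect u_s (SD 4°) is a single additive offset on γ∞ shared
across conditions, giving a clean repeated-measures correlation
structure.  Frames realise the latent angle exactly: the injury point is
a fixed hinge, the base ray drifts sinusoidally (amplitude 1°, period
30 min, random phase per leaf) to exercise the α-subtraction, and the tip
ray sits at δ₀ + γ relative to the base ray.  I.i.d. Gaussian coordinate
noise (SD 0.05 mm on 8–10 mm arms, ≈ 0.3–0.4° of angle noise) models
tracking error.  Defaults: 17 subjects, one frame per 30 s over 55 min,
evaluation at 1, 5, 10, 20, 40, 55 min.

The generator emulates angle-level structure only: it does not render
images, model correlated tracking error, point occlusion, or leaf-shape
change.  Passing recovery tests therefore demonstrate correctness of the
angle algebra and the inference pipeline, not robustness to real tracking
pathologies.

A `null_scenario` sets every γ∞ to 0 with identical τ, so the subject
offset enters all conditions identically and the condition-effect null
holds exactly; 1,000 replicates of the full simulate–score–test pipeline
keep the nominal 5% level within the exact binomial 99% interval.

**Tensile records.**  Displacement grows at strain_rate·L₀ per second
(defaults 0.002 s⁻¹, 5 Hz).  Stress is linear at slope E up to 70% of the
strength, then follows a concave parabola with an abrupt tangent drop at
yield (to 25% of E) peaking exactly at the strength, then a short rupture
tail at 35% of peak force — so maximum-force recovery is exact and the
peak precedes the final sample.  The transverse image pair is consistent
with the true Poisson ratio over the linear range.

**Turgor profiles.**  Turgor = mean + slope·(depth − mean depth) + noise,
truncated positive; defaults (44 cells, mean 0.042 MPa) match the scale
of pressure-probe campaigns.

All generators consume a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical text
exports.

## Numerical and interface choices

* Text interchange only: CSV with `repr`-formatted floats, so
  write∘read is the identity byte for byte; readers report malformed rows
  with line numbers and reject duplicate (subject, condition, time) keys.
* The pipeline writes a manifest (version, config hash, seed, input
  checksums) sufficient to reproduce any run exactly.
* Degenerate inputs fail loudly: coincident tracked points, empty tensile
  records, non-positive geometry, missing design cells (no imputation),
  constant input to Spearman's ρ.
* The 33% r.h. condition that exists in some experimental protocols is
  not part of the default four-level design; the ANOVA accepts any number
  of levels, so adding it is a scenario edit, not a code change.

## Known limitations

* The tissue-modulus coefficients are calibrated, not derived; the
  relation should be re-calibrated before use on species with markedly
  different cell-wall volume fractions or turgor ranges.
* Mauchly's interaction test needs n − 1 ≥ (a−1)(b−1) subjects; below
  that only the Greenhouse–Geisser correction (still defined via the
  pseudo-covariance trace ratio) is informative.
* The large-sample Spearman p uses the t approximation, adequate for the
  n ≈ 44 use case but not exact under heavy ties.
* Sealing kinetics beyond a saturating exponential (e.g. overshoot,
  bi-phasic drying) are outside the generator's vocabulary.
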