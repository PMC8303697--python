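# Methods

## Scope and data

The package reproduces a density-driven excluded-volume analysis of
sugar–denaturant counteraction on a globular protein. All primary inputs
are small printed tables shipped with the package:

- `data/species.tsv` — molar masses, effective hard-sphere diameters σ and
  salt stoichiometry for water, four sugars, two molecular denaturants and
  three salts (with their ions).
- `data/solutions.tsv` — the 30 measured solution densities at 25 °C
  (pure water, binaries, ternaries).
- `data/rnase_dsc.tsv` — the measured per-solution DSC summary
  (T_d, ΔH_d, CU, ΔG_d(25 °C)) for RNase A at pH 7.0.

No instrument files are parsed; raw thermograms are represented as plain
two-column (°C, kJ K⁻¹ mol⁻¹) arrays and, since none are deposited,
emulated by the synthetic generator.

## Packing model

Water molarity is recovered from the mass balance
[H₂O] = (ρ − Σ c_j M_j)/M_w with M_w = 18.015 g/mol; sugars are treated as
anhydrous (a dihydrate mass would break the balance against the measured
densities). Salts enter the packing sums only as their ions. Number
densities use N_A/10²⁷ = 6.02214×10⁻⁴ (mol/L)⁻¹ Å⁻³, kept in a single
constant. The ξ_i coefficients are plain sums over species; ξ₃ ≥ 1 is
rejected as unphysical. Temperature is recorded with each recipe but does
not enter the packing (densities were measured at 25 °C).

A `water_override` argument lets a tabulated (rounded) water molarity stand
in for the mass-balance value when byte-level agreement with a printed
table is wanted; it is off everywhere by default.

## Cavity work

Classic scaled particle theory for a hard convex body in a hard-sphere
mixture. For a spherocylinder of radius a and cylinder length l the mean
curvature radius is R_m = a + l/4 and the surface measure (area/4π) is
S_m = a² + al/2, giving

ΔG_c = RT[ −ln(1−ξ₃) + (6ξ₂/(1−ξ₃))R_m + (12ξ₁/(1−ξ₃) + 18ξ₂²/(1−ξ₃)²)S_m ].

l = 0 is exactly the spherical case, which the tests verify to machine
precision over random packings. The pressure–volume term of full SPT is
implemented but off by default: at 1 atm it contributes < 1 kJ/mol even for
the 15 Å sphere, well below the precision of the hard-sphere diameters.
R = 8.31446 J K⁻¹ mol⁻¹; energies in kJ/mol; default temperature 298.15 K.

Reproduction accuracy against the published 30-row cavity-work table is
0.25 % or better in ΔG_c and ΔΔG_c and ≤ 2 kJ/mol in ΔΔG_c′ (the residual
reflects the printed inputs carrying only 3–4 significant figures).

## Protein geometry

The native/denatured pair is a geometric idealization of a 138-residue
globular protein, not a structure-derived surface: sphere a = 15 Å versus
spherocylinder a = 6 Å, l = 117 Å, constrained to equal van der Waals
volume within 3 Å³ of 14,137 Å³ (volume change on unfolding is negligible
at 1 atm). SASA is the closed-form parallel body at the 1.4 Å water probe.
Conformational entropy uses 19.0 J K⁻¹ per residue; when the decomposition
is applied to the experimental RNase A data the chain length 124 is used
and flagged in the output, because the 138-residue model geometry carries
~79 kJ/mol more chain entropy — enough to flip the sign of the inferred
attraction residual for the weakest excluded-volume solutions (water, TMU).
With n_res = 124 the residual ΔE_a = ΔG_d − ΔΔG_c + TΔS_conf is negative
for all 30 solutions (−285 to −66 kJ/mol), as expected for a term dominated
by the larger attraction surface of the unfolded chain; it is reported only
as a qualitative residual.

## DSC analysis

The two-state excess heat capacity is evaluated in log-space
(K/(1+K)² = sech²(lnK/2)/4) so the wings underflow gracefully. The fit is
unweighted least squares (`scipy.optimize.curve_fit`, trust-region with
bounds T_d within the scan and ΔH_vH ∈ (0, 2000] kJ/mol), initialized at
the peak position and the closed-form peak height ΔH_vH²/(4RT_d²). The
equilibrium constant carries no ΔC_p term by default — ΔC_p,d is obtained
afterwards from the ΔH_d-versus-T_d slope across solutions, mirroring the
two-stage experimental procedure — but a Kirchhoff variant
(ΔH(T) = ΔH + ΔC_p(T − T_d), plus the sigmoidal step under the peak) is
available through `two_state_excess_cp(kirchhoff_dcp=...)`.

Baseline handling: a straight line is fitted to a pre-transition (native)
window of ≥ 5 points and subtracted across the scan. Over a 70 °C scan a
one-sided baseline is fragile — a slope error δb from noise in the window
biases the integral by roughly δb·(scan width)²/2, and at 1 kJ K⁻¹ mol⁻¹
noise this alone can move ΔH_cal by > 20 %. The subtraction therefore
accepts an optional post-transition window that anchors the far end of the
line; the recovery experiments use it (native 20 °C → T_d − 15, post
86–90 °C), and with it the worst-case errors over 20 parameter sets × 5
seeds are 0.06 K in T_d, 0.9 % in ΔH_vH and 0.035 in CU. The native window
should end ≥ 15–20 °C below the midpoint: closer windows pick up the early
transition wing and bias both the baseline and any cross-solution ΔC_p
regression.

ΔH_cal is a trapezoid on the measured grid (no resampling); non-decaying
tails raise a warning rather than an error. ΔC_p,d regression is ordinary
least squares of ΔH_d on T_d (slope invariant to °C/K shifts). On the 30
tabulated scans it gives 5.8 ± 1.0 kJ K⁻¹ mol⁻¹ (r = 0.73), consistent
with the published 6.4 ± 0.7 band that was estimated on a larger 45-scan
set. Gibbs–Helmholtz uses the standard constant-ΔC_p form, zero at T_d by
construction; recomputed ΔG_d(25 °C) values agree with all 30 printed
integers within 1 kJ/mol (the printed integers appear to mix rounding
conventions, so ±1 is the honest comparison).

## Synthetic thermograms

`synthetic.generate` draws cp(T) = b₀ + b₁T + f_D·ΔC_p,step + two-state
peak + ε with ε i.i.d. Gaussian — the simplest defensible model of a
blank-subtracted trace from a modern power-compensation DSC; real
instruments add correlated (1/f and thermal-lag) noise that this generator
deliberately omits, so recovery tests certify the analysis pipeline, not
instrument robustness. Defaults span the experimental regime: T_d 45–70 °C,
ΔH_vH 300–470 kJ/mol, 20–90 °C grid at 0.1 °C (a 1 °C/min scan at typical
sampling), noise 0.5 kJ K⁻¹ mol⁻¹. Randomness is
`numpy.random.default_rng(seed)` (PCG64), platform-stable; a fixed seed
reproduces curves and batch manifests exactly.

## Numerical conventions

- Temperatures: °C at every I/O boundary, kelvin in all thermodynamics
  (offset 273.15). Reference temperature 298.15 K.
- Energies kJ/mol; heat capacities kJ K⁻¹ mol⁻¹; lengths Å.
- The worked study tables are rounded for output (ΔG_c to 0.1 kJ/mol,
  ξ₃ to 3 decimals); all comparisons in tests run at stated tolerances,
  not on the rounded strings.
- Degenerate inputs fail loudly: over-full recipes (negative water),
  ξ₃ ≥ 1, salts without ion lists, baseline windows off-grid, all-equal
  T_d in the regression.

## Problem sizes

Everything is desk-scale: 30 solutions, 12 species, 701-point synthetic
scans, 100-curve recovery experiments; the full test suite and all
analysis drivers complete in seconds on one core.

## Known limitations

- Hard-sphere SPT ignores attractive interactions entirely; the attraction
  term is only ever inferred as a residual, never computed.
- One fixed spherocylinder stands in for the whole denatured ensemble.
- Counteraction is scored by the sign of ΔT_d with no threshold; the
  single negative pair (NaClO₄ + fructose, −0.4 °C) sits at twice the
  stated ±0.2 °C midpoint uncertainty.
- The generator's white-noise idealization above.
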