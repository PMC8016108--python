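# Methods

## Model

The follicle sinus complex is reduced to a planar ("pseudo-3D")
quasi-static structure: an Euler–Bernoulli beam for the whisker shaft, a
much stiffer beam for the follicle wall, and six linear springs. Springs
act along the single plane of whisker motion; because compression and
tension are sign changes of the same linear spring, one spring per station
represents tissue acting all around the shaft. Only one follicle is
deflected at a time, so neighbouring follicles and distant facial tissue
are collapsed into rigid ground behind the two external springs.

Discretisation: four whisker beam elements (hair bulb → cavernous sinus →
ring sinus → entrance → external stub), three wall elements, six springs;
20 DOFs in total (translation + rotation at each beam node, translation
only at the two ground nodes). Element stiffness matrices are the standard
cubic-Hermite bending matrix (entries 12EI/L³, 6EI/L², 4EI/L, 2EI/L) and
[[k, −k], [−k, k]]; assembly scatters them into a dense 20×20 symmetric
matrix. The deflection enters as an essential boundary condition — a
prescribed rotation θ̄ = −10° at the whisker's entrance node — enforced by
the penalty method together with the two fixed ground translations. The
nodal solve is a dense `numpy.linalg.solve`; at 20 DOFs nothing sparser is
warranted.

Displacement fields are reconstructed per element from the nodal solution
with cubic Hermite shape functions. Because all loads are concentrated
spring forces at nodes, the cubic is the *exact* solution of
EI u‴(x) = V(x) between nodes, so the reconstruction introduces no
discretisation error beyond the model itself. The wall profile f(x) is the
linear interpolant of the wall nodal translations; the wall's flexural
rigidity is 10⁴ × the whisker's, which keeps f(x) affine to ~10⁻⁴
relative. The shear V(x) = EI u‴ is piecewise constant.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| E (whisker) | 3.5 | GPa | keratin shaft modulus |
| R (base radius) | 75 | μm | 150 μm diameter near the base |
| L (follicle length) | 1 | mm | measured follicle length |
| k₁ (hair bulb) | 10³ | N/m | intermediate; negligible effect at the RS |
| k₂ (cavernous sinus) | 10⁴ | N/m | S-region baseline (see Calibration) |
| k₃ (ring sinus) | 10⁵ | N/m | S-region baseline; blood-pressure proxy |
| k₄ (entrance) | 10⁶ | N/m | ≥ 100 (k₅+k₆): whisker pivots at the entrance |
| k₅+k₆ (external) | 10⁴ | N/m | E_skin · L with E_skin = 8 MPa |
| k₆/k₅ | 7/3 | – | skin end stiffer than the deep (fat) end |
| spring stations | 0, 0.3, 0.6, 1 | ·L | HB, CS, RS, entrance |
| wall rigidity factor | 10⁴ | – | rigid wall within the 20-DOF layout |
| deflection | −10 | deg | positive = rostral |
| β (penalty) | 10⁷ × mean diag K | – | see Numerical choices |

All internal computation is SI (m, Pa, N/m, rad); config files use μm, mm,
GPa, MPa, N/m and degrees with unit-suffixed keys, converted exactly at the
I/O boundary.

Because the load is a prescribed rotation, displacements are invariant
under a uniform rescaling of EI and all six spring constants; only
stiffness *ratios* shape the profile. Changing E, I alone rescales the
balance between beam and springs and therefore the displacement magnitudes.

## Calibration choices

Two quantities are not fixed by anatomy and are documented here as this
package's calibration:

* **Cavernous-sinus station 0.3 L.** The station is a free parameter of the
  model; 0.3 L places it midway between hair bulb and ring sinus. The
  k₁-spread summary statistics are sensitive to it: moving it across
  0.25–0.40 L moves the mean ring-sinus spread over 0.366–0.439 μm and the
  cavernous-sinus spread maximum over 14.4–9.1 μm, so cross-study
  comparisons of those scalars should fix this station first.
* **Sweep baseline (k₂, k₃) = (10⁴, 10⁵) N/m.** An S-region pair used as
  the base state of the external-support and blood-pressure sweeps,
  consistent with the pressure sweep starting at k₃ = 10⁵ N/m.

## Profile classification

r(x) is classified by its number of axis crossings: C (0), S₁ (1), S₂ (2).
Crossings are counted on (0, 0.95 L): endpoint samples are excluded, as is
the entrance boundary layer above 0.95 L, and samples with |r| below
10⁻³ × max|r| are ignored. The boundary-layer exclusion exists because the
entrance spring k₄ is stiff but finite: every solved profile carries a
real recoil excursion of order 0.1 μm immediately below the entrance
(reaction force / k₄). That excursion is invisible at plot scale and not
part of the C/S/S taxonomy, but its relative amplitude (up to ~4% of
max|r|) overlaps that of genuine ring-sinus excursions, so no amplitude
threshold can remove it; a positional exclusion can, and makes the class
label independent of sampling density (verified by dense-grid recounts).
The 0.05 L layer width mirrors the ring-sinus window half-width.

Feasibility against the ex vivo data requires |r(0.6 L)| < 4.8 μm
(strict inequality; 12 μm for the relaxed variant), constant sign of r on
[0.55 L, 0.65 L], and that sign opposite to the deflection direction
(defined as the sign of the external tip's displacement). Under these
constraints only S-shaped profiles survive; the compliant (k₂, k₃) corner
is C-shaped and excluded. Feasibility is *not* monotone in k₃: the
magnitude criterion alone is (|r(0.6 L)| falls as k₃ rises), but at high
k₃ the deep crossing migrates into the ring-sinus window and the
sign-constancy criterion fails, so the feasible set is a band in k₃.

## Numerical choices

* **Penalty factor.** β = 10⁷ × mean(diag K) by default; β = 10⁷ E is
  selectable (`penalty_mode="modulus"`). The diagonal-scaled form is
  dimensionally consistent and keeps the penalised matrix comparably
  conditioned across unit systems. Both are validated against a
  Lagrange-multiplier solver that enforces the constraints exactly;
  agreement is ~10⁻¹¹ relative at the default β. The penalty error decays
  as 1/β until it reaches the float64 roundoff floor (~10⁻¹¹ relative,
  from β ≈ 10⁵ × mean diag onward).
* **Conditioning.** The global matrix mixes translational (m) and
  rotational (rad) DOFs, so its raw condition number is large (~10¹⁹)
  even though the solve is backward-stable and accurate; solver health is
  therefore judged by the relative residual (≤ 10⁻⁸ required) rather than
  by the condition number, which is reported only on failure.
* **Sampling.** Profiles default to 201 equispaced points on [0, L]; all
  qualitative results are verified stable on 10⁴-point grids.
* **Degenerate inputs.** Zero deflection yields the zero solution and a
  `DegenerateProfileError` from the classifier; zero spring stiffnesses are
  permitted (the element contributes nothing); duplicate constraints,
  out-of-range DOFs and non-positive geometry raise descriptive errors.

## Sweep design

Grids are logarithmic throughout. 1-D sweeps use 9 points per decade-range
(k₁ ∈ [10², 10⁶]; totals ∈ [10⁴, 10⁵]; ratios ∈ [1/20, 20]; k₃ ∈
[10⁵, 10⁶]); the (k₂, k₃) feasibility map uses 13 points per axis over
[10³, 10⁶]²; the k₁ sweep's (k₂, k₃) grid is 4×4 over [10³, 10⁶] ×
[10⁴, 10⁶]. r(0.6 L) is monotone in k₁, so the k₁ spread (max − min) is
set by the grid endpoints and insensitive to k₁ grid density. The
cavernous-sinus spread maximum is taken within ±0.05 L of the CS station
(the ring-sinus window convention) on the most compliant k₂ column. The
whole pipeline is deterministic — identical configs produce bit-identical
CSVs. Plot generation mirroring the sweep figures is deliberately out of
scope; the CSV/JSON outputs carry the full content.

## What the defaults do and do not show

The default configurations *are* the study conditions: all headline
scalars are recomputed from them, not stored. The model is quasi-static
and planar; it brackets deformation profiles and their parameter trends,
not absolute tissue strains, and cannot address collisions, vibrations,
texture or airflow. Mechanoreceptor firing is outside the model: r(x) is
an indirect predictor of receptor load, modulated by local tissue
stiffness the model does not resolve. With the calibration fixed as
documented, the computed ratio-sweep percentage (51.3%) and
cavernous-sinus spread maximum (12.9 μm) land close to the reference
values for those experiments, while the mean ring-sinus spread computes to
0.383 μm against a reference 0.286 μm — within the sensitivity range of
the undocumented cavernous-sinus station noted under Calibration.
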