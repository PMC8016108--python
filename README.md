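# follisim

Beam-and-spring finite-element simulation of how a whisker (vibrissa)
deforms *inside* its follicle sinus complex (FSC) when deflected.

## The problem

Whiskers carry no mechanoreceptors along their length: everything a rodent
senses is transduced by receptors packed inside the follicle at the whisker
base. How the whisker shaft deforms against those receptors cannot yet be
imaged in an intact follicle, so it must be inferred mechanically.
`follisim` is for sensory neuroscientists and biomechanicists who want a
quantitative, reproducible estimate of the whisker's deformation profile
inside the follicle — during passive touch and during active whisking — and
of how that profile shifts with muscle tone and sinus blood pressure.

## The model

The whisker is an Euler–Bernoulli beam (E = 3.5 GPa, base radius
R = 75 μm, I = πR⁴/4) running along the follicle axis x ∈ [0, L],
L = 1 mm. The follicle wall is a second, effectively rigid beam. Tissue
couples them through four internal springs placed at anatomical stations —
hair bulb (k₁, x = 0), cavernous sinus (k₂, 0.3 L), ring sinus (k₃, 0.6 L)
and entrance (k₄, L) — while two external springs tie the wall to ground at
its deep end (k₅) and at the skin (k₆), standing in for intrinsic muscle
and surrounding tissue. Default stiffnesses (N/m): k₁ = 10³, k₂ = 10⁴,
k₃ = 10⁵, k₄ = 10⁶, k₅ + k₆ = 10⁴ with k₆/k₅ = 7/3.

The structure is discretised into 13 elements with 20 degrees of freedom.
A 10° whisker deflection is imposed as a prescribed rotation at the
entrance node via the penalty method (β = 10⁷ × mean diagonal of K by
default), the ground translations are fixed, and the 20×20 system
**K** d = **f** is solved directly. Continuous profiles are reconstructed
by cubic Hermite interpolation of the nodal solution:

* u(x) — absolute whisker displacement,
* f(x) — follicle-wall displacement (affine, since the wall is rigid),
* r(x) = u(x) − f(x) — relative displacement, the quantity that loads the
  mechanoreceptors.

Profiles are classified by the number of times r(x) crosses the resting
axis: **C** (0), **S₁** (1) or **S₂** (2). An ex vivo imaging experiment
constrains feasible profiles: |r| at the ring-sinus level must stay below
4.8 μm (12 μm relaxed) and r may not change sign within the ring-sinus
window [0.55 L, 0.65 L], where it must point opposite the deflection.

## Worked example

```bash
$ follisim profile --out demo
class=S1 feasible=True r(RS)=2.954 um force=0.2954 N
wrote demo/profiles.csv
```

Under the default calibration the whisker takes an S₁ ("hook") shape,
crossing the resting axis once at 0.506 mm — just below the ring sinus. Its
relative displacement at the ring-sinus level is 2.95 μm, inside the
4.8 μm ex vivo bound (hence `feasible=True`), and the internal force it
exerts on the ring-sinus tissue is k₃ · r(0.6 mm) ≈ 0.295 N. The CSV holds
the sampled profiles (x in mm; u, f, r in μm; shear V in N):

```
x_mm,u_um,f_um,r_um,V_N
0.0,23.280399176222797,29.389609283820157,-6.109210107597359,0.006109210107597296
0.005,23.11027558157914,29.179758796096632,-6.069483214517494,0.006109210107597296
```

The four sweep experiments are exposed the same way:

```bash
$ follisim sweep-k1 --out demo        # hair-bulb spring sensitivity
mean spread at RS: 0.383 um
$ follisim map-k2k3 --out demo        # C/S1/S2 map + ex vivo feasibility
$ follisim sweep-support --out demo   # muscle tone: total + balance of k5,k6
$ follisim sweep-pressure --out demo  # sinus blood pressure via k3
```

Each writes a tidy CSV plus a JSON metadata file recording the exact grid
and base parameters. `follisim fixtures` emits the named YAML
configurations (`paper_default`, the four sweep setups, and the relaxed
12 μm variant); `--config` feeds any of them back in.

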