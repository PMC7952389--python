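# Methods

`iminoshift` predicts the chemical shifts of RNA imino groups — the N1–H1 of
guanine and N3–H3 of uridine, observable only when the base is hydrogen
bonded — and models the physics that shapes them. This note documents the
models, the parameters that matter, the numerical choices, and what the test
suite does and does not establish.

## The base-pair triplet model

Within an A-form helix the shielding environment of an imino group is
dominated by its own base pair and the two flanking pairs. A *triplet code*
writes those three pairs as three two-letter fields, each with the base on
the strand of the central imino nucleotide first, read 5′→3′ on that
strand (e.g. `UA-GC-GU`). Central pairs are restricted to the four
imino-bearing types (GC, UA, GU, UG); either neighbor may be any of the six
duplex pairs (GC, CG, AU, UA, GU, UG), giving 6 × 4 × 6 = 144 codes.

The predictor is a lookup table mapping each code to the central pair's
(¹⁵N, ¹H) shifts. The shipped table is *reconstructed* from a decomposed
representation

    δ_calc = δ_intrin(central) + δ_5(5′ pair) + δ_3(3′ pair)

whose 4 intrinsic + 24 + 24 terms ship with the package
(`data/decomposed_shifts.tsv`). Prediction of a residue requires its triplet
to be fully canonical and contiguous (i−1 pairs j+1, i+1 pairs j−1);
terminal pairs and pairs next to loops, bulges or noncanonical pairs are
never predicted from the table — the hybrid semiempirical route below is the
sanctioned path for those.

## Ring-current model

Each aromatic ring is modelled as a pair of circular current loops at ±z̄
above and below the base plane (z̄ = 0.64 Å, the mean 2p_z orbital height).
The shielding at a point is

    σ_rc = Σ_j i_j · B_j · G_j(ρ, z)

- `B_j = 3e²/(6π m_e a_j c²)`, evaluated in CGS-Gaussian units so σ is
  dimensionless; a_j = 1.39 Å for six-membered and 1.182 Å for five-membered
  rings, giving B = 3.227×10⁻⁶ and 3.794×10⁻⁶ respectively (regression
  constants).
- `G(ρ, z)` is the loop-pair geometry factor in complete elliptic integrals
  K and E, with ρ, z measured as ratios to a_j and the elliptic-integral
  *parameter* m = k² = 4ρ/((1+ρ)² + z±²) passed directly to
  `scipy.special.ellipk/ellipe`. G is even in z; the ρ=1, z±=0 loop-edge
  singularity is guarded (it cannot arise for physical z̄ > 0).
- `i_j` is the ring-current intensity relative to benzene. Two sets ship
  (`data/rc_intensity.json`): the proton set (Gua-5 0.81, Gua-6 0.49,
  Ade-5 0.95, Ade-6 0.83, Cyt 0.31, Ura 0.24) and a ¹⁵N set (2.60, 0.11,
  3.57, 0.06, 0.84, 1.32) calibrated against the triplet table. Chemical
  shift follows as δ = −σ × 10⁶ ppm: positive intensity on the ring axis
  shields (upfield).

Ring planes are fitted by singular-value least squares over all ring atoms
(robust to puckered rings in crystal structures; a 3-atom cross product is
not used). The normal's sign follows the atom traversal sense and is
irrelevant downstream. Local magnetic anisotropy is not modelled separately;
it is absorbed into the calibrated intensities.

### Intensity-factor calibration

`calibrate_intensity_factors` minimizes Σ(δ_rc − δ_table)² over the six
intensities across all 144 triplets, after removing a per-central-pair-group
mean (the intrinsic shift of each group is adjusted so calculated and
tabulated shifts share the same mean). Because δ_rc is linear in the
intensities this is an exact linear least squares, solved directly — no
starting point, deterministic by construction. The design uses the central
imino nucleus probed by all rings of the two flanking pairs. Under 0.1 ppm
table noise the parameter standard errors are ≈0.04–0.11, so the small
six-membered-ring factors are determined only to within ~±0.1 absolute;
the dominant five-membered purine factors are determined to a few percent.

## Electric-field model

Polar groups polarize the N–H bond through their Coulomb field; the
first-order proton shift is δ_ef = −A·E(XH)×10⁶ with A = −2.98×10⁻¹² esu⁻¹
and E(XH) the field at the H position projected onto the X→H unit vector.
Charges are the Amber ff94 nucleic-acid set (`data/ff94_charges.tsv`, in
elementary-charge units, summing to −1 per internal ribonucleotide),
converted to esu; distances in cm, so A·E is dimensionless. A field pointing
from X toward H deshields the proton. No distance cutoff is applied (1/r²
decay suffices at motif scale). Higher-order terms, polarizability
anisotropy and solvent fields are out of scope, and **no ¹⁵N version
exists** — the calculator refuses non-proton targets.

## Idealized A-form builder

`build_aform_duplex` places rigid bases (standard reference-frame
coordinates, heavy base atoms + C1′) on an idealized fiber A-RNA helix:
helical twist 32.7°, rise 2.81 Å, x-displacement −4.4 Å, inclination 15.7°.
The implied local step parameters (twist ≈31.5°, roll ≈+9°, slide ≈−1.6 Å,
rise ≈3.38 Å) match published analyses of fiber A-RNA; the generated WC
C1′–C1′ distance is 10.80 Å (regression value). G·U wobbles are built from
the WC template by sliding the uridine rigidly ~2.2 Å toward the major
groove so that G(N1–H1)···O2(U) and G(O6)···H3–N3(U) hydrogen bonds form at
2.6–3.1 Å. Imino protons are placed 1.01 Å from the nitrogen along the
in-plane C–N–C bisector when absent from the input (no force-field
relaxation is performed). Ring-current shifts are tolerant of moderate
geometry differences, and the calibration step absorbs much of the residual
structure-source dependence; nevertheless absolute ring-current values from
different structure generators differ at the 0.05–0.3 ppm level, which is
the main systematic limit of the semiempirical route here.

## Decomposition procedure

`decompose_lookup` inverts the reconstruction: for each central pair and
each fixed neighbor on one side, the six lookup shifts obtained by varying
the other side are offset so that their mean matches the mean calculated
ring-current shift of the varied pairs (both bases of the varied pair
contribute; the central nucleus is the probe). The six repetitions per
(neighbor, central) are averaged into 24 five-prime and 24 three-prime
contributions; intrinsic shifts are the means of the 36 residuals per
central pair. Feeding the decomposition the same ring-current values that
generated a table makes it the exact inverse of reconstruction (round-trip
error < 10⁻¹³ ppm). When real ring currents from the internal builder are
used, the ¹⁵N intensities are first recalibrated against the table on the
same structures — the same pipeline order used to produce the shipped
table — and the recovered intrinsic G-C shifts agree with the shipped
values within 0.11 ppm (¹⁵N) and 0.04 ppm (¹H).

## Dataset re-referencing and outlier trimming

Referencing errors between NMR datasets are additive, spectrometer-wide,
per-nucleus offsets. `build_lookup_table` aligns datasets sequentially: the
first dataset (assumed DSS-referenced) seeds the table with zero offset;
each subsequent dataset receives the closed-form least-squares offset (the
mean residual against the table means over common motifs, per nucleus,
computed against the table built from the *other* datasets), and the table
is updated after each dataset. Three full passes are run by default.

Trimming uses a 3σ rule with two deliberate choices:

- the candidate record is excluded from its own group statistics
  (leave-one-out mean) — with the record included, a group of n ≤ 10 can
  *never* flag anything at 3σ since max |z| = (n−1)/√n;
- the scatter scale is pooled per nucleus across all motif groups rather
  than taken per group: per-group rms at n ≈ 10 is so noisy that a 3σ rule
  either over-trims (~3–8%, with a trimming spiral) or lets pairs of
  outliers in one group mask each other. Groups with fewer than three
  records are never trimmed.

Trim flags are re-evaluated every pass (records can be re-admitted), and
trimmed records are excluded from both the offset fits and the table means.
On synthetic corpora (10 datasets, 0.05 ppm noise, 5% outliers at 6σ) this
recovers offsets and table means at ~1 standard error, flags >99% of
planted outliers and trims <1% of clean records. Raising the threshold
monotonically decreases the trimmed count.

Motif-tagged records (e.g. loop anchor residues) participate in alignment
exactly like triplet codes; reference values for such motifs are
user-supplied. Dataset input is TSV (`label  code  nucleus  ppm`).

## Register-shift predictions

For excited-state work, `register_shift_delta` reports |Δω| = |δ_ES − δ_GS|
between two codes in ppm and Hz. The proton frequency is the stated
spectrometer field; the ¹⁵N frequency is field × 81.08/800 MHz (81.08 MHz
at an 800 MHz spectrometer). `enumerate_register_slides` enumerates every
code change reachable by sliding one strand of a five-pair context by one
nucleotide: the central residue keeps its base but pairs with the partner
of its former neighbor. On the shipped table the slide map splits into two
clusters — slides that flip the central pair between GC↔GU or UA↔UG produce
roughly tenfold larger combined shifts than type-preserving slides.

## Synthetic-data generator

`synth_shift_datasets` emulates the statistical structure of a multi-source
shift corpus: a shared true table, per-dataset uniform(−0.5, 0.5) ppm
per-nucleus referencing offsets (the first dataset exact), Gaussian
per-record noise of 0.05 ppm, and 5% gross outliers at 6σ by default. All
randomness flows through one seeded `numpy.random.default_rng`. What it
does *not* emulate: assignment errors that are systematic rather than
gross, condition-dependent (temperature, pH, Mg²⁺) shift perturbations that
are *non-uniform* across residues, heteroscedastic noise between motifs,
and incomplete per-dataset coverage of the code space. Passing recovery
tests therefore demonstrate the estimator's correctness under the additive
offset + noise + gross-outlier model, not robustness to structured
artifacts in public-archive data.

## Numerical choices and degenerate inputs

- Elliptic integrals use the *parameter* convention m = k².
- Table values are carried at 2 decimals as tabulated; predicted sums are
  reported at 2 decimals with round-half-even.
- Collinear ring atoms, zero-length bonds, empty source sets, missing
  charge entries and loop-edge evaluation all raise or warn explicitly.
- Residue numbering is taken verbatim from input files; generated duplexes
  number chain A 1…n (5′→3′) and chain B n+1…2n (5′→3′ on its own strand).

## Known limitations

- The lookup route applies only to fully canonical, contiguous triplets;
  everything else needs a 3D structure (hybrid route) and inherits its
  accuracy from that structure.
- Calibrated ¹⁵N intensities are effective parameters: they absorb magnetic
  anisotropy, geometry bias of the structure source, and any systematic
  table error; they are not transferable ring-current strengths.
- Uridine ¹⁵N is the weakest spot of the semiempirical route (dynamic GU
  pairs, imperfect base-plane geometry).
- Tertiary contacts, Mg²⁺ binding and non-GU mismatches are outside the
  model; the electric-field term exists for protons only.
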