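# iminoshift

Prediction of RNA imino-group chemical shifts (¹H^N and ¹⁵N) from secondary
structure, and the semiempirical shielding models behind them.

Imino protons — G N1–H1 and U N3–H3 — are the workhorse probes of RNA NMR:
they are observable exactly when a base is hydrogen bonded, so their
chemical shifts encode secondary structure directly. `iminoshift` is built
for spectroscopists who want to predict imino shifts of helical RNA,
validate assignments, or interpret relaxation-dispersion Δω values of
invisible excited states in terms of alternative secondary structures.

## The model

The shifts of an imino group in an A-form helix are determined to high
accuracy by its **base-pair triplet**: the central pair plus the 5′ and 3′
neighboring pairs, written as a three-field code such as `UA-GC-GU` (first
letter of each field = base on the strand of the central nucleotide).
With 6 possible neighbors, 4 imino-bearing central pairs and 6 neighbors,
there are 6 × 4 × 6 = 144 codes. Each code maps to a (δ¹⁵N, δ¹H) pair via
a lookup table reconstructed from a decomposed representation

    δ_calc = δ_intrin(central) + δ_5(5′ pair) + δ_3(3′ pair)

The neighbor terms are, physically, ring-current shifts. The package
therefore also implements:

- the **Johnson–Bovey ring-current model**, σ_rc = Σ i_j B_j G_j(ρ, z),
  with B_j = 3e²/(6π m_e a_j c²) in CGS units, loop-pair geometry factor G
  in complete elliptic integrals, ring radii 1.39/1.182 Å, loop height
  z̄ = 0.64 Å, and both the proton intensity set and a ¹⁵N-calibrated set;
- **intensity-factor calibration** (least squares over all 144 triplets
  with per-central-pair mean centering);
- the **electric-field proton shift** δ_ef = −A·E(NH)×10⁶
  (A = −2.98×10⁻¹² esu⁻¹, Amber ff94 partial charges);
- an **idealized A-form duplex builder** (fiber A-RNA parameters, G·U
  wobbles included) and a PDB reader (gemmi);
- **dataset re-referencing**: building a shift table from many sources with
  per-nucleus offset alignment and iterated 3σ outlier trimming;
- **register-shift predictions** |Δω| (ppm and Hz) for excited-state
  secondary-structure verification.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Predict the imino shifts of a 13-mer hairpin with a five-pair stem:

```sh
$ printf 'CGGAGAAACUCCG\n' > seq.txt
$ printf '(((((...)))))\n' > ss.txt
$ iminoshift predict --seq seq.txt --ss ss.txt
residue	base	code	n15_ppm	h1_ppm	note
2	G	CG-GC-GC	147.07	12.52
3	G	GC-GC-AU	147.49	12.60
5	G	-	-	-	not predictable (noncanonical context): no contiguous flanking base pairs
10	U	CG-UA-CG	162.92	14.29
13	G	-	-	-	not predictable (noncanonical context): no contiguous flanking base pairs
```

G3 sits in the `GC-GC-AU` triplet, so its prediction is the tabulated sum
149.92 − 0.25 − 2.18 = 147.49 ppm (¹⁵N) and 14.01 − 0.36 − 1.05 = 12.60 ppm
(¹H^N). G5 borders the loop and G13 is terminal: no canonical triplet, no
table prediction (the hybrid ring-current route covers such residues when a
3D structure is available).

For excited-state work, the shift change when a ground-state triplet slides
into a G·U wobble:

```sh
$ iminoshift register-shift --gs GC-GC-AU --es GC-GU-AU --field 800
gs GC-GC-AU  es GC-GU-AU
15N: 4.28 ppm  347.0 Hz
1HN: 1.85 ppm  1480.0 Hz
```

The proton moves about four times as many Hz as the nitrogen — the reason
joint ¹H/¹⁵N relaxation dispersion is so informative for register shifts.

The same functionality is available as a library
(`iminoshift.predict_imino_shifts`, `iminoshift.register_shift_delta`,
`iminoshift.rc_shift_at_nucleus`, `iminoshift.build_lookup_table`, …).

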