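# Methods

## The screening model

`omescan` scores the hypothesis "this ribose carries a 2'-O-methyl group"
against a density map, residue by residue, in three steps:

1. **In-silico methylation.** For each candidate residue the methyl carbon
   (atom name CM', element C) is constructed from internal coordinates on the
   C1'–C2'–O2' frame: bond O2'–CM' of 1.43 Å and angle C2'–O2'–CM' of 113°,
   standard 2'-O-methyl nucleoside stereochemistry (wwPDB component A2M).
   Both are `AdductSpec` fields; the whole chemistry — target residue codes,
   parent atoms, adduct name/element, probe extension — is data, so other
   residue or even side-chain modifications can be screened by supplying a
   different adduct definition (JSON/YAML).
2. **Torsion selection.** With the parent geometry fixed, the adduct has one
   internal degree of freedom: the torsion about O2'–CM'. A full-circle scan
   (default step 5°) picks the torsion maximizing steric clearance — the
   minimum over all non-exempt heavy atoms of (distance − sum of van der Waals
   radii); an overlap of 0.6 Å or more counts as a clash (the widely used
   interactive-modelling default). Atoms within two covalent bonds of the
   adduct (O2', C2') are exempt. Optionally (on by default) the torsion is
   then settled into the density by maximizing
   J(τ) = map(CM'(τ)) − λ·max(0, −clearance(τ)), a coarse full-circle scan
   followed by nested local scans to 0.02° resolution. λ defaults to 10× the
   map RMS per Å of overlap, keeping both terms on comparable scales. This
   density-guided refinement is a deterministic stand-in for settling adducts
   with map-restrained molecular dynamics: with the environment held rigid,
   the MD's effective search space for the adduct collapses onto this one
   torsion. The rest of the model never moves — that deliberately isolates
   the signal (extra density at the methyl position) from conformational
   confounds, at the price of ignoring whatever relaxation of neighboring
   residues a full MD would allow.
3. **Scoring.** Sc_MapVal is the trilinearly interpolated map value at CM';
   the second probe is placed by prolonging the O2'–CM' bond to 2.4 Å
   (`probe_extension`), and Sc_FallOff = Sc_MapVal / map(extended probe).
   The probe direction is taken from the final (post-refinement) O2'→CM'
   vector. Candidates are ranked by Sc_MapVal descending (ties broken by
   chain, then residue number — a total order, so ranks are
   permutation-invariant); Sc_FallOff strictly greater than 1.5 sets the
   falloff flag.

Degenerate inputs are handled explicitly rather than silently: residues
missing a frame atom are reported as excluded with the atom named; collinear
frame atoms raise (the torsion is undefined); probes outside the map are a
hard per-site error that excludes the site from the ranking with a note — a
scored model must lie inside its map, and the tool does no model–map fitting.
A fully caged site is still scored (at the least-bad torsion) but carries a
`clash` note.

### Division guard

Experimental maps are full of near-zero and negative values outside the
molecular envelope, and Sc_FallOff is a ratio. When |denominator| ≤ ε × map
RMS (ε = 0.05 by default) the falloff is reported as undefined — the record
keeps its rank but can never pass the falloff flag. This keeps spurious
near-infinite ratios out of reports. RMS here is the RMS deviation from the
mean, the MRC2014 header convention.

### Numerical choices

- Interpolation is trilinear: exact at grid nodes and exact for affine fields,
  which the test suite exploits as closed-form oracles. Fractional grid
  coordinates within 1e-9 of a node are snapped so node queries return stored
  values bit-exactly despite origin/voxel roundoff.
- Torsion-scan ties go to the smallest angle; scan angles are normalized to
  (−180°, 180°].
- The density-guided refinement uses only argmax comparisons (no
  value-dependent step placement), so refinement commutes exactly with
  rescaling the map; together with the ratio form of Sc_FallOff this makes
  the entire screen's decisions invariant under map scaling, and Sc_MapVal
  exactly proportional to it.
- Maps are reindexed to (x, y, z) on reading, honouring the MAPC/MAPR/MAPS
  axis words; the ORIGIN record wins over start indices when both are present
  and inconsistent (a warning is logged), since the two MRC dialects diverge
  in the wild. Written maps always use x,y,z order, the ORIGIN record, and
  recomputed header statistics.
- Model reading keeps the first model block only, keeps the highest-occupancy
  alternate conformer per atom, and drops hydrogens (the screen is heavy-atom
  only). Author residue numbering is used everywhere, matching how
  modification sites are reported in the field.

## The synthetic fixture generator

`make_toy_rna(n, frac, seed)` builds n idealized adenosines (heavy atoms from
the chemical component dictionary bundled with biotite, phosphate dropped) at
uniformly random positions and orientations in a box sized to n, subject to
two spacing rules: all O2'–O2' pairs at least `min_spacing` (default 8 Å)
apart, and no two residues' atoms closer than 4 Å. The second rule is ours:
it keeps decoy probe circles out of neighboring residues' density, so a decoy
score reflects that residue alone. Exactly round(n·frac) residues, chosen at
random, receive a real CM' atom built by the same adduct machinery the screen
uses, at a random clash-free torsion — the screen's refinement has to find
it. Everything is driven by one `numpy` generator seeded from `seed`;
coordinates are bit-for-bit reproducible.

`simulate_map` renders each heavy atom as an isotropic Gaussian of
σ = 0.425 × `resolution_proxy` (FWHM ≈ the nominal resolution; 3 Å by
default, i.e. σ = 1.275 Å), truncated at 4σ, with amplitude 1 or the atomic
number (default), on a grid of 0.5 Å voxels covering the model plus 6 Å of
padding, plus i.i.d. Gaussian noise of chosen sd. Optional extra point
densities can be injected to emulate unattributed features (ions) next to a
ribose — the main false-positive mechanism on experimental maps, where an
adjacent blob lifts Sc_MapVal into the top ranks but, lacking a peak at the
predicted methyl that falls off along the bond, fails the falloff flag.

What this surrogate does and does not show: it reproduces the one feature the
screen keys on (modified riboses carry extra, localized methyl density;
unmodified ones do not) with closed-form, testable kernels. It has no solvent,
no B-factor variation, no anisotropy, no map-model misalignment, no chain
connectivity and no conformational error, so passing tests validate the
scoring and ranking machinery — not the screen's behavior under those
experimental nuisances. One quantitative artifact is worth knowing: with
Gaussian kernels, a decoy's probe pair brackets the steep outer tail of its
own O2' density, so decoy falloff ratios in a noise-free synthetic map are
*high* (≈ exp((2.4² − 1.43²)/2σ²), ~3 at σ = 1.275), higher than true sites'
(~1.9). Sc_FallOff therefore separates true sites from *adjacent-density*
false positives (its purpose), not from empty-space decoys — on experimental
maps the latter rank too low in Sc_MapVal to matter, and in noisy synthetic
maps their near-zero denominators scatter their ratios. Ranking and recovery
conclusions are unaffected: true sites separate from decoys by ~1.6× in
Sc_MapVal in the standard fixture.

## Default screen conditions

| parameter | default | meaning |
|---|---|---|
| bond_length | 1.43 Å | O2'–CM' bond |
| bond_angle | 113° | C2'–O2'–CM' |
| probe_extension | 2.4 Å | O2'→extended-probe distance |
| falloff_threshold | 1.5 | strict lower bound for the falloff flag |
| denominator_epsilon | 0.05 | falloff guard, fraction of map RMS |
| torsion_step | 5° | clash/refinement scan step |
| clash overlap | 0.6 Å | vdW overlap counting as a clash |
| resolution_proxy | 3.0 Å | synthetic kernel FWHM |
| voxel_size | 0.5 Å | synthetic grid spacing |
| noise_sd | 0 | synthetic map noise |

The standard validation fixture is 40 adenosines with 8 methylated (20%),
mirroring a screen of known sites among many candidates at a scale that runs
in seconds; the acceptance script also exercises noise at 10% of the
noise-free map's peak. These sizes were chosen as the smallest at which
recovery statistics are meaningful; recovery there is 8/8 in the top 8
(noise-free, with the lowest-ranked true site still 1.6× above the best
decoy) and 8/8 in the top 10 under noise.

## Known limitations

- The environment is rigid; a modification that requires local rearrangement
  to be visible will be scored at the unrearranged geometry.
- One conformation per model: alternate locations are collapsed to the
  highest-occupancy conformer before screening.
- The tool ranks and flags; deciding whether a high-ranking,
  falloff-failing site is an ion, noise, or something interesting remains a
  visual-inspection task downstream.
- No map sharpening, masking, or resolution estimation; the screen scores
  whatever map it is given and records its checksum and statistics for
  provenance.
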