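# Methods

## Model

The solvent accessible surface area (SASA) of a set of spheres with
centers xᵢ and radii rᵢ is the area of the surface traced by the center
of a probe sphere of radius r_p rolling over them — equivalently, the
boundary of the union of the *extended* spheres Rᵢ = rᵢ + r_p.  Both
implemented algorithms approximate the exposed area of each extended
sphere independently, after a shared neighbor search:

**Lee & Richards slicing.**  Each atom is sliced individually into
`n_slices` slabs of thickness Δz = 2Rᵢ/n_slices along z.  At each slab
*midplane* z the atom's circle has radius ρᵢ = √(Rᵢ² − (z−zᵢ)²); a
neighbor j whose sphere cuts the plane leaves a circle of radius ρⱼ at
in-plane distance δ.  If δ + ρᵢ ≤ ρⱼ the slice is fully buried; if
δ ≥ ρᵢ + ρⱼ or δ + ρⱼ ≤ ρᵢ it is untouched; otherwise the buried arc is
the interval β ± arccos((δ² + ρᵢ² − ρⱼ²)/(2δρᵢ)) around the in-plane
center azimuth β (argument clamped to [−1, 1]).  Intervals are normalized
to [0, 2π) with wrap-around splitting, sorted and merged; the exposed
fraction f contributes f·2πRᵢΔz (the Archimedes strip area).  Because the
strip areas telescope, an isolated sphere is exact at *any* slice count,
and slicing per atom means small atoms automatically get thinner slabs.

**Shrake & Rupley test points.**  `n_points` unit vectors are generated
once by the golden-angle spiral — point k of n at z = 1 − (2k+1)/n,
azimuth k·π(3−√5) — scaled to Rᵢ around xᵢ.  A point is accessible iff it
lies strictly outside every neighbor's extended sphere; the area is the
accessible fraction times 4πRᵢ².

**Neighbor search.**  Atoms are hashed into a cubic grid with cell side
2·(max rᵢ + r_p), so any intersecting pair lies within adjacent cells and
a query scans only the 3×3×3 neighborhood.  Two atoms are neighbors iff
‖xᵢ − xⱼ‖ < rᵢ + rⱼ + 2r_p, strictly: tangent spheres remove a
measure-zero surface set and do not occlude.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `probe_radius` | 1.4 Å | water-sized probe, the field's convention |
| `n_slices` | 20 | L&R slices per atom; ε ≈ 0.03 Å²/atom on dense packings |
| `n_points` | 100 | S&R points per atom; chosen for quick runs, since test points win over slices only at low resolution |
| `n_workers` | 2 | per-atom loop partitioning; never affects values |

The default algorithm is Lee & Richards.  The CLI's `-n` flag sets the
resolution in the selected algorithm's native unit (slices or points).

## Radius assignment

ProtOr group radii: C3H0 1.61, C3H1 1.76, C4H1/C4H2/C4H3 1.88, all N
1.64, carbonyl/carboxyl/phosphate O 1.42, hydroxyl/ester O 1.46, S 1.77,
P 1.80, Se 1.90 Å.  The published ProtOr tables cover proteins; the
nucleotide, capping-group and water entries here apply the same class
logic to those residues' atoms (sp³ C 1.88, aromatic C–H 1.76, bare sp²
C 1.61, ester and hydroxyl O 1.46, phosphate O 1.42).  Polarity follows
the NACCESS tradition: carbon-centered classes are apolar, everything
else (N, O, S, Se, P centers) polar; users can override any of this with
a config file.  Hydrogens and HETATM records are excluded at parse time
by default; when HETATMs are included, acetyl, NH₂ and water are
recognized, a residue whose atom names all match the standard nucleotide
map is classified as a (modified) nucleotide, and anything else falls
back to the Mantina et al. main-group element radius with a warning.
Atoms classified by element fallback are aggregated into a separate
"unknown" polarity bucket so the apolar/polar/unknown split always
partitions the total exactly.

## Numerical choices

- Slab evaluation at midpoints: second-order accurate, and keeps ρᵢ > 0
  so the arc formula never divides by zero.
- Accumulation order is fixed (ascending atom, slice/point index) and
  each atom's area is written to its own slot, so results are bitwise
  independent of worker count; workers are threads (the per-atom loop is
  embarrassingly parallel and numpy releases the GIL in the hot kernels).
- Degenerate configurations: a sphere inside another gets exactly zero
  (the containment test uses ≤, per slice); of two coincident atoms with
  equal extended radii the higher-index one is deemed buried and only the
  lower-index one counts, decided exactly rather than through rounding-
  sensitive boundary comparisons.  A test point exactly on a neighbor's
  surface is otherwise treated as buried; the set of such points has
  measure zero and in floating point essentially never occurs off the
  constructed degenerate cases.
- Selection evaluation and aggregation are pure sums over per-atom areas,
  so the algebraic identities (complement, partition by chains or
  residues) hold to accumulation round-off.

## What the synthetic data emulates — and what it does not

`random_packing(200, box 30 Å, radii 1.5–2.0 Å)` reproduces protein-like
atom density: each atom has ~8 neighbors and the packing contains both
fully buried and nearly free atoms.  `protein_rna_complex_pdb` emits
fixed-column PDB text for four chains (ALA/GLY/SER protein strands,
full-heavy-atom A/U/G/C nucleotides) packed around a common axis so that
chains bury surface against one another.  Atom *placement* is random
jitter, not stereochemistry: bond lengths and angles are unphysical.
Passing tests therefore demonstrate correct parsing, classification,
geometry, aggregation and selection arithmetic on realistic densities
and name sets — they do not validate against experimentally determined
structures, and totals printed for synthetic complexes have no
biological meaning.  On real PDB files the same defaults reproduce the
conventional L&R/ProtOr numbers to within the slice-placement freedom of
the algorithm (different implementations place slices differently; totals
agree to a fraction of a percent, not bitwise).

## Problem sizes

The test suite and the acceptance script size their simulations to run on
one CPU core in well under a minute each: the precision comparison uses
200-atom packings (20 in the suite, 5 in the script) with the 1000-slice
L&R total as reference A_ref and ε = |A − A_ref|/N as the per-atom error;
the Monte-Carlo verification of the two-sphere closed form uses 10⁶
surface samples for the reference configuration and 2·10⁴ for each of 50
random configurations (3σ agreement).

## Known limitations

- Only the first MODEL and the primary altloc conformer (blank or 'A')
  of a PDB file are read; occupancy-weighted multi-conformer SASA is out
  of scope.
- No analytic surface or gradients; no second test-point lattice (the
  double-cubic-lattice refinement of S&R is not implemented).
- No relative accessibility (per-residue percentages against Gly-X-Gly
  reference states) and no mmCIF input.
- The selection grammar is a small Pymol subset: resn, resi (with
  '+'-lists and dash ranges), chain, name, symbol, and/or/not with
  parentheses — no within/byres/property selectors.
- Exact per-atom agreement with other L&R implementations requires their
  (unpublished) slice placement; totals agree closely but not bitwise.
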