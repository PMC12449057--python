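# Methods

## The occluded-surface model

The package treats a structure as a set of hard spheres at the atoms' van
der Waals radii. Each sphere is covered with area-carrying surface dots;
from every dot an outward radial normal is traced (the radial direction is
the only surface normal of a sphere). The first intersection with a
neighbouring sphere within the water diameter `d_w` marks the dot occluded
with normal length `L`; a normal that travels farther than `d_w` means a
water molecule could sit in the gap, so the dot is treated as solvent-facing
and disregarded. Dots that fall *inside* another sphere (overlapping,
covalently bonded geometry) are removed before ray casting — burial and
occlusion are distinct: overlap removes surface, proximity occludes it.
Because bonded-atom overlap is handled by this removal step, every other
atom in the structure acts as a potential occluder and no connectivity
information is needed.

Per atom, the occluded surface packing density is

    OSP = Σ_occluded A_d (1 − L_d / d_w) / Σ_retained A_d .

The numerator weights each occluded patch by how close the neighbouring
surface sits (weight 1 at contact, 0 at the water cutoff); the denominator
is the atom's retained (non-buried) dot area. OSP is 0 for an isolated atom
and → 1 for an enclosed atom with vanishing normals. Normalising by
*retained* rather than total sphere area is a deliberate choice (both
appear in the literature); it is what makes the enclosed-atom limit reach
exactly 1, and it is configurable in spirit: the raw areas are in every
output table, so the alternative normalisation is one division away. An
atom whose entire surface is buried has no retained dots; it is reported as
a zero-area packing with OSP 0 and flagged by `n_dots == 0` rather than
being assigned the physically suggestive value 1 — downstream residue means
are then explicit about what was measurable.

Residue OSP is the unweighted mean of member-atom OSPs (an area-weighted
variant is available via `area_weighted_residues`); structure summaries use
the sample (n−1) standard deviation, with SD defined as 0 for a
single-residue structure.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d_w` | 2.8 Å | water diameter; maximum normal extension |
| `density` | 5.0 dots/Å² | surface dots per unit area (~182 dots on a carbon sphere) |
| `method` | `fibos` | dot lattice: Fibonacci spiral or classical radial |
| radii | bundled table | Bondi-style protein vdW radii, element fallback + per-atom overrides |
| `mad_k` | 3.0 | influence-screen threshold: median + k·MAD |
| `side` | `gap` | which dispersion the influence screen targets (sd_b − sd_a) |

The dot count per atom is `max(1, round(density · 4πr²))`; per-dot areas
are rescaled to sum exactly to the sphere area, so total area is conserved
at any density. Heavy atoms only are read by default (hydrogen content
differs systematically between experimental structures and computed
models; packing comparisons must be on a common atom set), and waters /
HETATM groups are excluded unless requested, since their presence is
exactly the kind of difference the comparison stage is meant to expose,
not absorb. Alternate locations resolve to the highest-occupancy conformer
(ties: first in file).

## Dot lattices

The Fibonacci lattice places dot *i* at height `z_i = 1 − 2(i+½)/n` with
azimuth `i` times the golden angle π(3 − √5); the ½ offset keeps dots off
the poles, and every dot carries area fraction `1/n` exactly. The classical
radial construction uses latitude bands equally spaced in polar angle about
the z axis; dots within a band are equally spaced in azimuth with counts
apportioned to band circumference (largest-remainder rounding, minimum one
dot per band), and each dot carries its band's exact area fraction divided
by the band count. The band grid uses a 1.5:1 azimuthal-to-polar patch
aspect ratio: this preserves the axial anisotropy and pole/equator area
spread that characterise the historical construction at every dot count (a
square-patch grid is nearly as uniform as the Fibonacci lattice, which
would erase the very contrast the two methods are meant to exhibit). Both
lattices are deterministic; identical inputs give bit-identical clouds.

## Numerical choices

Ray–sphere intersection solves `|o + t·d − c|² = r²` per dot/neighbour pair
and takes the smallest admissible root: the smaller positive root outside a
sphere, `t = 0` for an origin inside one (occluded at zero length). Ties
between occluders resolve to the lowest atom index — deterministic, and
exercised by the oracle-equivalence tests. Neighbour lookup uses a k-d tree
with cutoff `2·r_max + d_w`, which provably contains every possible
dot-to-surface hit; the engine is therefore exactly equivalent to all-pairs
ray casting (asserted record-for-record against a plain-Python brute-force
oracle). Burial uses a strict inequality: a dot exactly on a neighbour's
surface is retained. Rigid-motion invariance holds when the dot lattice is
co-rotated with the frame; regenerating the lattice in a rotated frame
changes individual dots by discretisation, though the aggregate OSP is
stable (the invariance test co-rotates).

## Comparison statistics

Residues are paired 1:1 on (chain, residue number, insertion code, residue
name); unmatched residues are reported, never silently dropped. Wilcoxon
signed-rank drops zero differences (Wilcoxon's original convention) and
uses mid-ranks for ties; for n ≤ 25 the exact two-sided p-value is computed
by dynamic programming over the 2ⁿ equiprobable sign assignments (valid
with mid-rank ties, verified against exhaustive enumeration), and the
tie-corrected normal approximation is used above. All-zero differences give
p = 1 and d = 0 by convention. Paired Cohen's d is mean(diff)/sd(diff).

The influence screen estimates each residue's contribution to the
dispersion statistic — by default the gap `sd_b − sd_a`, which cancels the
static contribution of residues that are extreme on *both* sides (a buried
residue inflates both SDs equally) and isolates residues that disperse one
side only. The default estimator is the jackknife, `score_i = T(all) −
T(without i)`; the analytic influence function of the standard deviation,
`IF(x) = ((x−μ)² − σ²)/(2σ)`, is available as an alternative mode (the two
agree in ranking; the jackknife approximates IF/(n−1) in scale). Residues
with scores above median + 3·MAD are flagged. The rule is scale-free: what
fraction of residues it flags depends only on the *shape* of the score
distribution, a fact that matters for interpreting null runs (below).

## What the synthetic fixtures emulate — and what they do not

The fixture generators produce sphere clusters with known geometry: dimers
(contact, overlap, isolation regimes with closed-form buried fractions), a
first coordination shell (a buried atom), cubic lattices, seeded random
clusters, a helical pseudo-peptide, and the *micelle* — a closed spherical
shell of 72 two-atom "dumbbell" residues used for paired-comparison
studies. In the micelle, residue sites sit on a Fibonacci lattice 4 Å
apart; each residue is a CA sphere plus a side-chain tip (alternating
CYS SG and SER OG, so the two vdW radii 1.80/1.52 Å create two clean
packing classes) at 3.5 Å along the outward radial. The closed surface
gives every residue an equivalent environment — no chain ends or corner
atoms with anomalous packing — and the tip's occlusion is dominated by its
own CA, so a displaced tip changes its own residue's OSP far more than its
neighbours'.

`make_perturbed_pair` emulates two determinations of the same chain: copy B
receives optional isotropic Gaussian jitter (σ) and optional planted
outliers — terminal side-chain-like atoms displaced 6 Å away from the
structure centroid, the "side chain extends away from its cluster into
solvent" event that motivates the influence screen. The study conditions
are: planted-recovery runs use pure displacement (σ = 0), and null
calibration runs use σ = 0.02 Å jitter with no outliers (`NULL_SIGMA`).
These two regimes are deliberately separate, for a statistical reason: the
median + 3·MAD threshold adapts to whatever dispersion is present, so in a
run containing background jitter the threshold scales with the jitter while
the maximum of ~70 near-Gaussian noise scores almost always exceeds a
2-MAD-ish cut — exact single-residue recovery *with* jitter is not
achievable by any threshold of this family, and a screen should not be
asked to distinguish a planted event from noise of its own magnitude. The
jitter scale for null runs keeps the influence response in its linear
regime (score ∝ (x−μ)·ε), where the near-two-class micelle makes scores
close to homoscedastic and the flagged fraction small; at large σ the
quadratic ε² term dominates and the score distribution acquires a χ²-like
right tail that any robust-null rule flags at 10–15% — a property of the
estimator, not a bug. Under the chosen conditions the screen recovers a
single planted displacement exactly in 20/20 seeds and flags a median of
≤ 5% of residues under the null.

What these fixtures do **not** emulate: real side-chain chemistry and
connectivity, backbone continuity, solvent and ligands, crystallographic
disorder, or the size and diversity of real experimental/model structure
pairs. Passing tests demonstrate that the geometry engine is exact, the
statistics match their definitions, and the influence screen is calibrated
in a controlled regime — not that any particular biological conclusion
transfers to real structures.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances: clusters of ≤ 20 atoms at ~200 dots/atom for oracle equivalence,
1000-dot lattices for uniformity and cap-fraction checks, and the 144-atom
micelle (20 planted + 20 null pairs) for the comparison stage. These sizes
make every check exact or tightly converged while keeping the whole suite
in the tens of seconds; the engine itself is vectorised per atom and
handles ordinary protein chains (10³–10⁴ atoms) without special handling.

## Known limitations

* Only fixed-column PDB input; mmCIF is out of scope.
* First-intersection normals: no re-entrant or multi-hit correction.
* No solvent-excluded (Connolly) surface and no probe-rolling SASA; the
  water diameter enters only as a normal-length cutoff.
* Parity with the legacy Fortran implementation of the radial lattice is
  not claimed; any circumference-proportional band lattice reproduces the
  qualitative anisotropy but not dot-for-dot output.
* The bundled radii are one published convention; users with a different
  convention should supply their own table (`--radii`).
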