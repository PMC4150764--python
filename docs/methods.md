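# Methods

`tfdna` analyzes how a TetR-family transcriptional repressor engages its
operator DNA, using CprB of *Streptomyces coelicolor* A3(2) — a
γ-butyrolactone-receptor homolog that binds a 22-bp semi-palindromic
consensus operator (CS, 5′-ACATACGGGACGCCCCGTTTAT-3′) as a dimer of dimers —
as the motivating system. This note records the models, conventions and
numerical choices behind each analysis, what the synthetic-data generators
do and do not emulate, and the known limitations.

## Structure model and PDB handling

Coordinates are held in a plain chains → residues → atoms hierarchy with
positions in Å. Parsing is delegated to gemmi; alternate locations are
collapsed at read time to the highest-occupancy conformer, ties broken by
file order (low-resolution TetR-family structures rarely carry informative
altlocs, so a single-conformer model is adequate). Waters are retained but
flagged and excluded from every geometric operator; hydrogens, if present,
are likewise kept but ignored — the structures of interest are ~3 Å
resolution and carry none. Writing uses fixed-width PDB records, and a
written file re-read and re-written is byte-identical over its ATOM block,
which makes file-level round-trip tests exact. Nucleotide residue names are
accepted as DA/DT/DG/DC or A/T/G/C and normalized internally. Chain ids are
restricted to one character on output (classic PDB dialect); mmCIF is not
supported.

Watson–Crick pairs are detected from three criteria evaluated on heavy
atoms only: base complementarity, C1′–C1′ distance within 8.9–11.9 Å, and
purine-N1/pyrimidine-N3 distance ≤ 3.5 Å. Unpaired nucleotides (e.g.
disordered termini modelled on only one strand) are reported as overhangs
and excluded from all helical statistics.

## Base-pair frames and step parameters

Base reference frames follow the standard reference frame for nucleic-acid
bases (x into the major groove, y toward the strand-I backbone, z along
helix advance): the standard-geometry ring of the observed base type is
least-squares superposed (SVD/Kabsch) onto the observed ring atoms, and the
resulting rotation + translation is the frame; the fit RMSD is carried on
the frame as a quality signal. A pair frame is the exact angular midpoint
(half-rotation about the common hinge) of the strand-I frame and the
strand-II frame flipped 180° about x, with the origin at the mean of the
two base origins.

Step parameters between consecutive pair frames use the mid-step-triad
construction of the 3DNA family: both frames are symmetrically rotated onto
the common mid-frame z-axis (each by half the RollTilt angle Γ about the
hinge z₁×z₂), twist is the signed x-axis rotation about that common z, the
hinge phase angle φ against the mid-frame y decomposes Γ into
roll = Γ·cos φ and tilt = Γ·sin φ, and (shift, slide, rise) are the origin
displacement expressed in the mid-step triad. The builder's inverse
transform is tested to reproduce all six parameters to < 1e-13 over broad
random ranges, and the generator→analyzer identity on (twist, rise, roll)
holds to the 0.1°/0.01 Å level demanded of it for roll ∈ [−8°, +8°].
Averages are arithmetic means with sample (n−1) standard deviations.

## Global bend

Two definitions are exposed because an "overall bend" of a finite helix is
not unique:

- **ends** (default): the angle between the mean base-pair normal of the
  first three pairs and that of the last three — an end-to-end statement of
  how much the helix entry and exit directions differ. A single 10° kink at
  a middle step reads back as 10.0°; a straight fiber reads 0°.
- **cumulative**: Σ√(roll² + tilt²) over steps, an upper bound in which
  opposing bends cannot cancel.

Neither is asserted against a crystallographic target, since uniform-roll
constructions show how strongly the number depends on the definition (a
uniform +5° roll over 21 steps gives an end-to-end bend of ≈3.6° but a
cumulative bend of 105°).

## Groove widths

Groove width at base-pair level *i* is the minimal cross-strand P–P
distance between the strand-I phosphate at level *i* and strand-II
phosphates in a fixed partner-level window, minus 5.8 Å for two
phosphate-group radii (the El Hassan–Calladine-style convention). In the
register used here — strand-II phosphates indexed by the pair level of
their residue — the minor-groove window is partner levels i−1…i−4 and the
major-groove window i−5…i−7. The windows are disjoint because the minor
P–P separation is the global cross-strand minimum and would otherwise leak
into the major window on deformed duplexes. Levels whose full window is
unavailable (chain termini, missing phosphates) are flagged not-measurable
rather than reported from a truncated window, which would bias the minimum
upward.

The fiber geometry underlying the synthetic duplexes places the phosphorus
at radius 8.91 Å (the classic B-DNA fiber value) with azimuth and rise
offset solved so the cross-strand P–P minima of the ideal fiber are
17.5 Å (major) and 11.7 Å (minor), i.e. widths 11.7 Å and 5.9 Å — the
canonical ideal-B values, with the 11.7 Å major-groove figure serving as
the fixed calibration anchor. The same solution independently reproduces a
physically correct ≈5.6 Å P(i)→C1′(i−1) backbone linkage, which is how the
mirror-image solution of the calibration was rejected.

## Synthetic generators

All generators are pure functions of (spec, seed).

- **Duplex builder**: standard-geometry base templates (ring atoms + C1′)
  stacked on pair frames generated by composing prescribed step transforms
  (defaults: twist 36.0°, rise 3.38 Å — 10 bp/turn B-form); the
  complementary strand is the reverse complement, flipped 180° about the
  pair x-axis. Each residue carries a 5′-phosphate group (P/OP1/OP2) placed
  by the fixed template above. The builder provides frames, steps and
  P-atom groove geometry exactly; it does not attempt refinement-grade
  sugar stereochemistry, sequence-dependent base geometry, or solvent.
- **Toy apo/bound complexes**: each prescribed hydrogen bond is a LYS-NZ /
  SER-OG donor–acceptor pair on a 25 Å grid (no accidental cross-slot
  contacts); retained pairs sit at 2.6–3.3 Å in both states, disrupted and
  formed pairs at ≥ separation_distance (default 7 Å, required to exceed
  the 3.5 Å cutoff) in the state where they are broken. The ground-truth
  ledger is returned keyed exactly as `diff_interface` reports, so recovery
  is testable for equality, not just counts.
- **Genomes**: i.i.d. bases at a prescribed GC fraction with motif copies
  planted at fixed positions, mutated at exactly the requested number of
  seeded mismatch positions, minus-strand plants inserted as reverse
  complements. Real intergenic structure (codon bias, repeats, skew) is not
  emulated; passing scan tests demonstrate coordinate/strand bookkeeping
  and score correctness, not sensitivity on real genomes.
- **Isotherms**: exact model heats plus i.i.d. Gaussian noise in kcal per
  mole of injectant. Real ITC artifacts (first-injection loss, baseline
  drift, heat of dilution trends) are not emulated; an optional
  first-injection drop and blank subtraction cover standard practice.

## ITC model and fitting

The per-injection heat model is the Wiseman construction for one or two
independent site classes on a macromolecule M titrated with ligand X:
cumulative heat Q = V₀·[M]·Σⱼ nⱼΔHⱼ·Kⱼ[X]free/(1+Kⱼ[X]free), with [X]free
from mass balance — a cancellation-safe closed-form quadratic for one
class, a bracketed Brent solve for two, both polished with clamped Newton
steps to a mass-balance residual below 1e-10 relative (verified on 1000
random draws). Each injection of volume v displaces cell content, so totals
carry the cumulative (1 − v/V₀) factor and the measured heat is
Qᵢ − Qᵢ₋₁ + (vᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2, normalized per mole injected.

Concentration convention: the cell macromolecule is accounted per protein
dimer (default 10 μM, i.e. half of 20 μM monomer) titrated with 120 μM
duplex, so a fitted stoichiometry n ≈ 0.5 reads "duplexes per dimer".
The injection schedule defaults to 25 × 1.5 μl into a nominal 200 μl cell
at 298.15 K, reaching a molar ratio of ≈2.25 duplex per dimer — enough to
pass both equivalence points of a two-class system. Simulation and fitting
share the convention, so recovery results are convention-independent.

Fitting minimizes least squares over (nⱼ, ln Kⱼ, ΔHⱼ) with bounded
trust-region steps, multi-started from seeded points dispersed over
Kd ∈ [1 nM, 100 μM] and the observed heat scale; the best optimum is kept
and asymptotic standard errors come from the Jacobian. Two-site results are
reported weakest class first (K₁ < K₂). Model comparison is reported via
small-sample-corrected AIC; no automatic selection is made. Wald 95%
intervals on ln K cover the generating value in ≥90% of noisy replicates
(50-seed calibration at 0.3 kcal/mol noise).

Derived quantities use ΔG = −RT ln K with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹
and TΔS = ΔH − ΔG. Note that a published (Kd, ΔH, ΔS) triplet is
overdetermined; this package always derives ΔS from the fitted Kd and ΔH
rather than fitting it independently.

## Interface contacts

Hydrogen bonds are heavy-atom donor–acceptor pairs within a cutoff
(default 3.5 Å) with no angular term — appropriate at ~3 Å resolution where
no hydrogens are modelled. Donor/acceptor status comes from fixed
dictionaries for the 20 amino acids (backbone N donor except proline,
backbone O acceptor, standard side-chain assignments) and the 4
deoxynucleotides (base edge donors/acceptors; phosphate and sugar oxygens
as acceptors). His ND1/NE2 and the Asn/Gln amide atoms are treated as both
donor and acceptor, reflecting crystallographic ambiguity. A looser 3.9 Å
all-atom count is reported separately for "contact" totals that include van
der Waals packing and is never called a hydrogen bond; aromatic/base
stacking is flagged by ring-centroid distance ≤ 5.5 Å and also kept out of
hydrogen-bond counts. DNA atoms are classified backbone if primed (sugar)
or phosphate, base otherwise.

The apo/bound interface diff keys bonds by (residue, atom-name) pairs after
applying a user-supplied chain correspondence: apo-only pairs are
disrupted, bound-only formed, common retained, and the distance of every
pair is reported in both states even when far beyond the cutoff (a
disrupted pair's separation in the bound state is itself the observable of
interest). The partition identities (disrupted ∪ retained = apo set,
formed ∪ retained = bound set) are property-tested on 100 random toy
ledgers.

## Disulfide geometry and strain

Bridges are described by χ1, χ2, χ3, χ2′, χ1′ with the IUPAC sign
convention; the SG–SG distance must be ≤ 2.5 Å. Handedness is the sign of
χ3 (negative: left-handed); the conformation class follows the common sign
taxonomy — spiral when χ2 and χ2′ share the sign of χ3, staple when both
oppose it, hook when mixed. Strain energy is the standard torsional cosine
series
E = 2.0[1+cos 3χ1] + 2.0[1+cos 3χ1′] + 1.0[1+cos 3χ2] + 1.0[1+cos 3χ2′]
  + 3.5[1+cos 2χ3] + 0.6[1+cos 3χ3] (kcal/mol),
with the force constants exposed in configuration because published
disulfide-analysis servers differ slightly in their constant sets; the
formula is 2π/3-periodic in the χ1/χ2 angles and non-negative by
construction.

## Quaternary angle and SASA

The dimer-of-dimers angle is measured at the centroid of all DNA heavy
atoms, between rays to the Cα centroid of each dimer — the DNA pivot is
chosen because the quantity describes how far the two dimers wrap around
the operator. Whether published values of this angle used Cα, all-atom or
domain-restricted centroids is generally unstated, so the number is
reported, not asserted.

SASA is Shrake–Rupley quadrature: per-atom area = (exposed points / total
points)·4π(r+probe)², with a deterministic golden-spiral point lattice
(default 960 points, probe 1.4 Å) and van der Waals radii C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å. Determinism makes reports byte-reproducible;
accuracy is ~1% against dense quadrature at 960 points and is verified in
tests against the closed-form two-sphere cap integral and an independent
Shrake–Rupley implementation. Agreement with totals computed by other
programs using other radius sets (e.g. refinement-package surface areas) is
explicitly not promised; comparative (apo vs bound) statements are the
supported use.

## Motif scanning

Scanning is ungapped Hamming-style similarity of a fixed-length IUPAC
consensus against every window, both strands (the minus strand scanned as
the reverse-complemented consensus so all coordinates stay 1-based
inclusive on the plus strand). Score is the count of compatible positions;
there is no position weighting — the search the package reproduces is a
fixed-string similarity lookup, and no similarity threshold is endorsed as
a default because none is canonical (min_score is a required parameter).
Conservation annotation marks a column '*' when all sequences agree, ':'
when at least two (but not all) agree, ' ' otherwise.

## Problem sizes used by the bundled checks

The bundled verification runs are desk-scale by construction: a 22-bp
duplex (21 steps, ~600 atoms), 25-injection titrations with 20 (one-site)
or 50 (two-site) fit starts, 100-slot toy interfaces, and 150–10,000 bp
synthetic genomes. These sizes make every check exact or
statistically stable while keeping the whole suite to well under a
minute of compute per module.

## Known limitations

- The duplex builder is not a stereochemistry engine: sugars are reduced to
  C1′, and OP1/OP2 are schematic. Analyses that only need ring atoms, C1′
  and P (everything in this package) are exact; downstream uses that need
  full backbones are out of scope.
- Contact detection has no angular or energetic term; at high resolution it
  will over-count relative to geometry-aware definitions.
- The two-site model treats site classes as thermodynamically independent;
  explicit inter-dimer cooperativity constants are not modelled (the
  two-class fit is the standard operational surrogate).
- Water-mediated contacts, electrostatics, pocket volumes and
  crystallographic statistics are out of scope.
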