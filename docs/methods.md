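# Methods

## Scope and data model

The package operates on two kinds of objects: atomic structures
(`gemmi.Structure`, read from PDB or mmCIF) and tidy measurement tables
(`pandas.DataFrame` with columns `construct, model, x, replicate, response,
unit`). Everything downstream — census, similarity search, fits,
stoichiometry, reports — is a pure function of these inputs.

## Coordination-shell census

**Shell definition.** A contact is any O or N atom (including water O,
excluding metal atoms) within a cutoff of a Na⁺ ion. The cutoff defaults to
3.0 Å: typical Na–O bond lengths are 2.3–2.5 Å, and 3.0 Å cleanly separates
the first coordination sphere from second-shell atoms for a hard monovalent
cation. The cutoff is configurable and the census summary records the value
used. Only ions with at least one protein-derived contact are reported as
sites. Hydrogens are ignored throughout: no criterion depends on H
positions, so protonation assignment is unnecessary. Donors are restricted
to O/N because Na⁺ is a hard cation; C and S contacts are never counted.

**Classification.** Side-chain donors are the named O/N atoms of standard
residues (Asp OD1/OD2, Glu OE1/OE2, Ser OG, Thr OG1, Asn OD1, Gln OE1,
Tyr OH, His ND1/NE2); backbone O and OXT are main-chain carbonyls; water O
is its own class; anything else is `other_hetero`, logged but never
dropped. A residue is *bidentate* when both of its carboxylate oxygens
(Asp OD1+OD2 or Glu OE1+OE2) contact the same ion.

**Statistics.** Coordination-number histograms, means and modes are
reported twice — over all donors and over protein donors only — because
"coordination number" in the literature sometimes excludes waters; both
variants are always emitted so the choice is explicit. Residue rankings
count distinct residues (per site) contributing at least one contact of the
class; the main-chain ranking is additionally emitted per contact. Modes
and rank ties break deterministically (smallest CN; alphabetical residue
name). The bidentate fraction is per acidic residue type: bidentate
residues over all residues of that type donating any side-chain contact.

The headline corpus claims about real structures (five-point mean
coordination, Asp as the most common side-chain donor, roughly half of
coordinating Asp bidentate) depend on a dated snapshot of the PDB and a
web-service clustering; they are not reproducible offline. The test suite
instead verifies *exact recovery*: a synthetic corpus constructed with a
given composition is summarized with exactly that composition. Passing
these tests shows the counting machinery is correct, not that any
particular database has those statistics.

## Corpus selection

Quality filters mirror a standard crystallographic survey: X-ray method,
0 < resolution ≤ 2.5 Å, R_obs ≤ 0.3, at least one protein chain of
40–100000 residues, no nucleic-acid chains, at least one Na⁺. Bounds are
read inclusively at the stated maxima. Missing required metadata raises
rather than silently passing. Redundancy removal is greedy clustering in
order of descending sequence length (id tiebreak): a sequence joins the
first cluster whose representative it matches at ≥ the identity threshold
(default 50%), else founds a new cluster — so representatives are pairwise
below threshold by construction. Identity is matches / alignment columns
with terminal-gap columns excluded, from a global alignment (match +1,
mismatch 0, gap open −2, extend −0.5, free end gaps) computed with
Biopython's `PairwiseAligner`. Biological-assembly operators are applied
when present in the file; otherwise the asymmetric unit is used with a
logged note. When altlocs are pruned, the highest-occupancy conformer is
kept (ties → altloc 'A') so each ion has a single shell.

## Site similarity

Sites are fingerprinted by ligand-class and residue-type multisets, two
motif flags (bidentate acidic residue; Ser/Thr side-chain oxygens at author
numbers i and i+1 on one chain with no insertion codes), and ion-centered
donor coordinates. Superposition minimizes RMSD over proper rotations about
the ion (determinant-corrected Kabsch) and over all class-preserving donor
correspondences, exhaustively — at coordination numbers ≤ 8 split into
classes this is at most a few hundred assignments. Reflections are
excluded because coordination chirality is physically meaningful; note that
highly symmetric arrangements (e.g. a planar square of same-class donors
plus an apex) are achiral under class-preserving correspondence and will
superpose onto their mirror image at RMSD 0, which is correct behaviour.
Sites with different class multisets raise a distinct "not comparable"
error rather than returning a large RMSD. Search ranking is RMSD-ascending
when a ceiling is given, otherwise by a shared-feature count (motif-flag
agreement plus class/residue multiset overlap); ties break on entry id so
results are independent of census order.

## Synthetic structures

Fixtures place donor atoms exactly at the requested bond length (default
2.4 Å) on ideal polyhedron vertices (octahedral, trigonal-bipyramidal,
square-pyramidal, tetrahedral) or in the fixed five-donor Na3-like
arrangement: bidentate Asp204 (carboxylate O–O separation 2.2 Å, both
oxygens at the bond length), Thr395 OG1, Ser396 OG, and the Ser392
main-chain carbonyl. Residues are minimal chemically plausible stubs —
backbone plus the atoms leading to the donor, placed radially outward so
that non-donor atoms stay outside the detection cutoff; only
donor-atom identity and position matter to the census, so rotamer realism
is deliberately not attempted. Jitter is isotropic Gaussian per ligand
atom; the ion is never jittered, keeping Na–donor distances interpretable.
Element fields are written explicitly so detection never guesses elements
from atom names.

## Electrophysiology simulation

Current-type responses (activation, inhibition) get multiplicative noise,
`response × (1 + N(0, σ))`, because oocyte current scatter scales with
amplitude; charges and reversal potentials get additive noise in measurement
units. No noise model is published for these protocols; the defaults used
in tests (5% relative for currents, 1 mV for reversal potentials) are
calibration choices representative of good two-electrode voltage-clamp
data, chosen once and documented here. All generators are seeded and
bit-exact reproducible.

## Fitting

All fits are unweighted least squares (`scipy.optimize.curve_fit`) on
replicate means with deterministic initialization: I_max (or Q range) from
the data extremes, midpoint parameters from a log-linear half-maximum
crossing, Hill slope and apparent valence starting at 1. Standard errors
come from the fit covariance. Non-convergence and out-of-window midpoints
(K_0.5 outside the tested range × [0.01, 100]) are flagged, with parameters
still returned. The model forms (Hill; single-site binding isotherm for
inhibition and Q_max suppression; two-state Boltzmann) are the canonical
transporter-literature choices consistent with every reported parameter;
no kinetic state model is attempted. For Na⁺ activation of a two-site
transporter the fitted K_0.5 is a lumped coefficient and n_H a lower bound
on stoichiometry — the package labels the Hill-based coupling estimate
accordingly. Inhibition fits emit both IC50 and the corrected K_i so either
convention can be compared. Responses may be pre-normalized to a reference
concentration (`normalize_to_reference`); fits are invariant to positive
rescaling except for the amplitude parameters, which scale linearly.

## Stoichiometry

The reversal-potential relation is derived from ΔG = 0 for inward
cotransport of n Na⁺ (+1 each) with one neutral sugar, membrane potential
inside-relative-to-outside:
`V_rev = (RT/F)[ln(Na_o/Na_i) + (1/n) ln(S_o/S_i)]`.
The Nernst-limit test (equal sugar in/out reduces to the Na⁺ Nernst
potential, ≈58.6 mV per decade at 22 °C) pins the sign convention.
Constants: R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹, T = 295.15 K (22 °C,
the oocyte recording temperature; RT/F ≈ 25.4 mV). Intracellular
concentrations are user inputs; simulations use oocyte-typical values
(Na_i = 10 mM, S_i = 0.05 mM) since inside concentrations are rarely
printed. n is estimated by ordinary least squares of V_rev on ln S_o, with
SE propagated from the slope SE; the fixed Na⁺ term only shifts the
intercept and is verified not to move the estimate.

## Comparative report

Fold changes are direction-annotated ratios with reciprocal antisymmetry;
labels round to the nearest integer above 10-fold and to one decimal below,
with raw ratios always carried alongside. Subtype selectivity is
K_i(hSGLT1)/K_i(hSGLT2) per inhibitor. The packaged parameter table
(`data/table1.csv`) is a transcription of measured constants with SEMs and
a provenance column; entries published only as bounds (">100 mM") are left
blank and never enter ratios. Ratio uncertainties are not propagated — the
SEMs are carried through unchanged for the user to treat as they prefer.

## Problem sizes and determinism

Test and acceptance workloads are desk-scale by design: 8-point dose grids
with 5 replicates, 6-point reversal series with 10 replicates, censuses of
tens of synthetic sites, clustering of a handful of sequences. These sizes
match the replicate counts of the emulated experiments (n ≥ 5–10 oocytes
per point) and keep every check deterministic and fast. Property-based
tests run derandomized with fixed example budgets.

## Known limitations

* The census trusts deposited ion assignments; it does not validate Na⁺
  against K⁺/Mg²⁺ mis-assignment or electron density, and computes no
  bond-valence sums.
* Greedy clustering is order-dependent by design (deterministic, but not a
  global optimum) and is not meant for database-scale inputs.
* The similarity search compares coordination shells only; it says nothing
  about fold or sequence relatedness of the parent proteins.
* Synthetic fixtures have idealized geometry and isolated sites; they do
  not model crystallographic disorder, occupancy < 1, symmetry-related
  shell completion, or second-shell effects, so census tests demonstrate
  correctness of the counting, not real-PDB statistics.
* The Boltzmann Q–V fit treats charge movement as a two-state process;
  multi-state relaxations are out of scope.
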