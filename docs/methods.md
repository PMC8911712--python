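# Methods

This note records the models and procedures implemented in `vocscreen`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices that affect results.

## Peak identification filter

A chromatographic peak is identified only if its spectral-library relative
standard intensity exceeds 600 and its signal-to-noise ratio exceeds
50 dB. Both thresholds are **strict** inequalities ("higher than",
"above"): a peak at exactly RSI = 600 or S/N = 50 is rejected. The filter
is order-preserving and idempotent; its defaults live in
`voc_profile.DEFAULT_RSI_MIN` / `DEFAULT_SNR_MIN`.

## Abundance table conventions

Percent abundances are used exactly as printed in the source table; sample
columns are **not** renormalized to 100% (one sample column sums to ≈112%,
and the normalization basis of such tables is generally unstated, so any
correction would be invented). "ND" (not detected) is treated two ways on
purpose: as *missing* for presence counts and per-sample rankings, and as
*zero* for abundance-weighted aggregations (group means, molar-content
coverage), since a compound below detection contributes no mass. Compound
class comes from the table's class column/section, never inferred from the
molecular formula — a C15H24 formula does not guarantee a sesquiterpene
skeleton. Decimal commas and `%` suffixes are accepted on input; canonical
output uses decimal points and bare numbers, and a parse → write → parse
round trip is the identity.

The packaged reference table (`vocscreen/data/table1.csv`) ships as data,
cell for cell as printed, including its quirks (a compound with blank
rather than "ND" cells, one entry with no CAS number). It anchors the
worked-example tests.

## Triage model

Pose scores are AutoDock-Vina-style affinities in kcal/mol, lower =
stronger. The first three poses per ligand are treated as replicates in a
one-way ANOVA over ligands followed by all-pairs Tukey HSD. Poses of one
ligand are **pseudo-replicates** — they are correlated samples of one
energy landscape, not independent docking runs — so the ANOVA p-values are
optimistic; the procedure is retained because the triage only consumes the
letter structure, not the p-values themselves.

The compact letter display uses the insert-and-absorb construction: start
with one column containing every ligand; for each significantly different
pair, split every column containing both; absorb columns that become
subsets. The construction guarantees both directions of the CLD invariant
(two ligands share no letter **iff** Tukey rejects their equality), which
the tests verify against an independent studentized-range computation.
Letters are assigned in ascending-mean order, ties broken by ligand id, so
the display is deterministic.

Classification is anchored on controls docked alongside the candidates
(the ANOVA must therefore include controls and candidates jointly):
TOP = shares a letter with the best positive control, WORST = shares with
the worst negative control, MIDDLE = neither. "Close to the anchor" is
operationalized as letter-sharing because that is what an annotated score
bar chart with ANOVA letters supports; a candidate sharing letters with
both anchors (possible in low-power panels) goes to the anchor with the
smaller absolute mean difference, and an exact tie is MIDDLE. Default
α = 0.05.

Group summaries report, per (site, group): compound count, mean score,
mean across-sample abundance (ND → 0), descriptor means, and class
composition percentages (summing to 100 within non-empty groups). The
"percent of molar content able to bind" aggregation is exposed as a
parameter (`groups`, `across`) rather than a fixed rule, because headline
numbers of that kind depend on whether MIDDLE compounds count and whether
sites are pooled — a reporting choice the data cannot decide.

## Descriptor correlogram

Authoritative descriptor values are ingested from delimited text
(mirroring the common practice of computing them with external property
calculators); the package computes only what structure alone determines:
molecular weight, N/O hydrogen-bond acceptor and NH/OH donor counts,
rotatable bonds, and `max_length`, the maximum pairwise interatomic
distance of the conformer *as given* (no conformer search, for
determinism). Pearson r and two-sided p are computed pairwise-complete per
(descriptor, site); cells with fewer than 3 pairs or zero variance are
undefined (NaN), never 0 — a constant vector has no correlation, not a
null one. No multiple-testing correction is applied by default (the
correlogram is exploratory); Benjamini–Hochberg adjustment is available as
`Correlogram.with_bh_adjusted()`.

A "molecular extensibility" descriptor is sometimes discussed alongside
maximal length; it has no standard formula and is not implemented —
unknown columns in an ingested table are kept and flagged instead.

## Contact areas

The contact-area definition is semantic: the area of atom *i*'s
probe-expanded sphere (R_i = r_i + 1.4 Å) that atom *j*'s probe-expanded
sphere excludes from a rolling water molecule. A null area means a water
could be interposed; larger areas mean tighter packing. The implementation
samples `n_points` (default 960) deterministic spherical-Fibonacci points
on each ligand sphere and attributes each buried point to the receptor
atom of deepest burial (minimum |p − c_j| − R_j, ties to the lowest
serial):

    A(i, j) = (4π R_i² / n_points) × #(points assigned to j)

Properties that hold by construction: A(i, j) = 0 exactly when the
expanded spheres are disjoint (at any n_points); the sum of A(i, ·) never
exceeds the expanded-sphere area 4πR_i²; no RNG enters, so results are
bit-reproducible at fixed n_points. For an isolated pair the exact answer
is the spherical-cap area 2πR_i·h, h = R_i − (d² + R_i² − R_j²)/2d; the
sampled estimate agrees within 2% at n_points = 10 000 over the interior
of the overlap interval, degrading only for caps a fraction of an Å thick
(lattice discretization, ~1/√n_points along the cap boundary).

Choices: the probe radius is the standard 1.4 Å water probe. Areas are
computed on ligand-atom spheres and attributed to receptor atoms
(directional) because the fingerprint assigns contact intensity to
receptor residues from ligand poses. Hydrogens are dropped by default
(docking outputs vary in protonation); waters likewise. Van der Waals
radii are Bondi's, with Fe at 2.00 Å (a common metallic convention; Bondi
has no Fe entry) and 1.70 Å + warning for unlisted elements. Cofactors
(heme, zinc, pterins) are part of the receptor.

The heme subsite partition (PDB v3 atom names) is: HFN = FE, NA–ND;
HCC = ring/methine/substituent sp2-region carbons (C1A–C4D, CHA–CHD,
CMA–CMD, CAB/CBB/CAC/CBC); HCR = propionate-chain carbons (CAA, CBA, CGA,
CAD, CBD, CGD); HCO = propionate oxygens (O1A, O2A, O1D, O2D). Placing the
methyl/vinyl substituent carbons in HCC rather than HCR is a judgment
call — "sp3 carbons that support the carboxylic groups" most naturally
means only the propionate chains — and the scheme is editable
(`SubsiteScheme.from_csv`).

Aggregation uses the simple pooled mean over the pose/ligand set (each
pose weighted equally, also across ligands with unequal pose counts);
contact frequency is the fraction of poses with any contact to the
residue. Exported maps are recentred to the geometric center of the atoms
involved in contacts and carry a 5 Å grid-spacing convention for plotting.

## Synthetic generators

`gen_scores` plants three candidate clusters: TOP-like at the best
positive-control mean (−9.0 kcal/mol), WORST-like at the worst
negative-control mean (−4.0), MIDDLE-like midway, with i.i.d. Gaussian
pose noise (default sd 0.25 kcal/mol, 3 poses). Two controls per role are
emitted, offset by 0 and +0.4 kcal/mol from the anchor means, so the
best/worst anchors sit exactly at the spec'd means. Gaussian noise is
chosen for analytic tractability of recovery thresholds; real docking
rescoring noise is neither Gaussian nor independent across poses, and
real panels have unequal cluster shapes — so a passing recovery test
demonstrates the classifier's behaviour under clean separation, not
field performance. The planted-recovery condition exercised in tests is
5/10/5 candidates, pose sd 0.05, adjacent-cluster separation 2.5 kcal/mol
(50× the noise), where ≥90% label recovery is required.

`gen_toy_complex` lays isolated atom pairs along x with ≥20 Å between
cells so no cross-pair contact is possible, and emits the closed-form
expected area per pair. Because the loader assigns radii by element, the
generator realizes a requested radius with the element of nearest Bondi
radius and reports the radius actually used (1.70 → C, 1.52 → O,
1.55 → N, 1.80 → S exactly).

`gen_peak_table` pins four boundary rows (RSI exactly 600, S/N exactly
50, just-above-both, just-below) before uniform sampling, so the strict
inequality is always exercised.

All generators are pure functions of their spec; the same spec gives
byte-identical output.

## Problem sizes

Default test and acceptance runs use: 50 random Tukey panels of 4–8
ligands × 3 poses; a 20-candidate planted triage panel; 25-point
closed-form contact grids at 10 000 lattice points; n = 200–400
correlation vectors. These sizes put every stochastic check well inside
its statistical tolerance while keeping a full run in tens of seconds.

## Known limitations

- Docking itself, ligand preparation, homology modeling and electron-
  density validation are out of scope; the pipeline starts from score
  tables and posed complexes.
- The triage inherits the pseudo-replication caveat above; its letters
  should be read as a reproducible grouping heuristic, not inference.
- Contact areas are sampling-based; exact tessellation would remove the
  ~1–2% cap-boundary error at the cost of determinism guarantees this
  implementation prioritizes.
- The reference abundance table reproduces its source as printed,
  including a sample column that sums to ≈112% and a text-vs-table
  disagreement about the rank of the dominant monoterpene in sample A.2
  (the table makes it rank 1 at 34.8%); the code always ranks by the
  table's numbers.
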