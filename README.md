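# vocscreen

Tools for profiling seed volatile organic compounds (VOCs) and triaging
their predicted affinities against anti-inflammatory protein targets.
The package was built around a concrete screening campaign: headspace
GC-MS volatiles of *Myracrodruon urundeuva* (aroeira) seeds docked against
the COX-1 active site and the two druggable pockets of inducible
nitric-oxide synthase (the active site, iNOSas, and the pterin cofactor
site, iNOScs) — but every stage is generic.

It is aimed at computational natural-products researchers who have (a) a
compound abundance table from GC-MS, (b) pose-level docking scores for the
identified compounds plus positive/negative control ligands, and
(c) posed ligand–receptor complexes in PDB format, and who want a
reproducible path from those inputs to ranked hits and interface
fingerprints.

## What it computes

**Volatile profile** (`vocscreen.voc_profile`). Parses compound ×
sample percent-abundance tables (not-detected cells, decimal commas, `%`
suffixes), ranks constituents per sample, tallies chemical classes
(monoterpenes / sesquiterpenes / other), and applies the peak
identification filter: a chromatographic peak is kept only if its spectral
library match quality RSI > 600 **and** its signal-to-noise ratio
S/N > 50 dB (strict inequalities).

**Control-anchored triage** (`vocscreen.triage`). With pose scores
s_{ℓ,1..m} (kcal/mol, lower = stronger) per ligand ℓ, the mean of the
first m = 3 poses enters a one-way ANOVA over ligands (poses as
replicates) followed by all-pairs Tukey HSD at α = 0.05, summarized as a
compact letter display (CLD). Candidates are classified per site:

- **TOP** — shares a Tukey letter with the best (most negative mean)
  positive control;
- **WORST** — shares a letter with the worst (least negative mean)
  negative control;
- **MIDDLE** — shares with neither (sharing with both resolves to the
  nearer anchor mean).

Cross-site set algebra then reports ligands TOP at several sites and
site-specific binders (TOP at exactly one site, WORST at the others).

**Descriptor correlogram** (`vocscreen.descriptors`). Pearson r (with
two-sided p) between each molecular descriptor (molar volume,
polarizability, miLogP, TPSA, parachor, H-bond counts, maximal conformer
length, ...) and per-site mean docking scores, pairwise-complete, in
"candidates + controls" and "candidates only" variants. Negative r marks
attributes that improve predicted affinity.

**Contact fingerprints** (`vocscreen.contacts`). For each ligand atom i
the van der Waals sphere is expanded by a water-probe radius (1.4 Å) and
sampled with a deterministic spherical Fibonacci lattice; a sample point
buried inside receptor expanded spheres is attributed to the atom of
deepest burial, giving pairwise contact areas A(i, j) in Å². A(i, j) = 0
exactly when a water molecule could be interposed between the atoms. For
an isolated pair the construction has a closed form (spherical cap,
2πR_i·h with h = R_i − (d² + R_i² − R_j²)/2d), which the test suite uses
as its oracle. Areas are aggregated per residue — with the heme prosthetic
group split into HFN (Fe + pyrrole N), HCC (porphyrin sp2 carbons), HCR
(propionate sp3 carbons) and HCO (carboxylate oxygens) — into mean contact
area and contact frequency across poses and ligands.

**Synthetic data** (`vocscreen.synthetic`). Planted three-cluster score
panels with known truth labels, toy complexes whose contact areas have the
closed form above, and peak tables straddling the RSI/S-N thresholds.

## Worked example

```python
import vocscreen as vs

profile = vs.load_reference_profile()          # packaged 23-compound table
print(vs.class_counts(profile))
# {'MONOTERPENE': 9, 'SESQUITERPENE': 8, 'OTHER': 6}
top, value = vs.summarize_sample(profile, "A.5")[0]
print(top.name, value)
# 3-Carene 55.2
print(vs.presence_across_samples(profile, "3-Carene"))
# 5

spec = vs.ScorePanelSpec(n_top=5, n_middle=10, n_worst=5,
                         pose_sd=0.05, seed=7, site_id="COX1")
scores, truth = vs.gen_scores(spec)
from vocscreen.triage import scoresets_from_frame
result = vs.triage_site(scoresets_from_frame(scores))
print(result.labels["TOP01"], result.labels["MID01"], result.labels["WRS01"])
# TOP MIDDLE WORST
```

The CLI mirrors the library: `vocscreen profile`, `vocscreen triage`,
`vocscreen overlap`, `vocscreen correlate`, `vocscreen contacts`,
`vocscreen simulate` (see `--help` on each).

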