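# Methods

## Score model

A screen is a table of raw docking scores, one per compound × target ×
receptor structure. Scores are dimensionless (MolDock-like), more
negative meaning better predicted affinity, stored at full input
precision. Files are comma-separated with a mandatory header; typographic
minus signs (U+2212), as typeset in journal tables, are normalized to
ASCII before parsing so printed tables can be transcribed verbatim.
Compound identity is the `compound_id` token alone; names are metadata.
Ingest rejects duplicate (compound, target, structure) keys; the
separate validator reports duplicates, missing (compound, target) pairs
and non-negative scores without raising.

## Ensemble aggregation and references

MD_i(t) is the arithmetic mean of a compound's scores over the receptor
structures docked for target t (two PDB entries per enzyme in the
motivating screen; one for PPO, where no second structure exists). The
reference score MD_r(t) is the minimum (most negative) MD_i(t) over all
compounds in the loaded table; ties break to the lexicographically
smallest compound id so outputs are deterministic. The reference pool is
whatever table is loaded — for a top-10 excerpt the global reference is
assumed to appear in it, which holds by construction of a top-N table.

## vMTi, wMTi, SR

vMTi sums MD_i/MD_r over the index targets (default: the three insect
targets EcR, PPO, DmAChE). With all scores negative each term lies in
(0, 1], the reference compound of a target contributes exactly 1 for it,
and vMTi is invariant to rescaling any one target's scores by a positive
constant — the properties that make it a multitarget measure rather
than a disguised average.

wMTi multiplies each term by a desirability coefficient n_t. Defaults
are +0.3 (EcR, PPO, DmAChE) and −0.3 (hAChE), giving the identity
wMTi = 0.3·vMTi − 0.3·(hAChE term), which the tests check to 1e−12.
Coefficients are configurable via YAML/JSON (`targets:` map plus
`index_targets:` list).

The selectivity ratio SR divides the DmAChE mean score by the hAChE one;
both negative, SR > 1 means stronger predicted binding to the insect
enzyme. A zero denominator leaves SR undefined and flags the compound.

Degenerate inputs: a compound whose MD_i is non-negative for some target
gets ratio 0 there (no affinity credit for a predicted non-binder) with
a warning; strict mode raises instead. A compound missing a required
target score is excluded from the index output and listed in the report,
because the sum is undefined; an opt-in flag imputes ratio 0 instead.
Internal arithmetic is double precision; the reporting layer rounds
half-away-from-zero to two decimals, matching the published tables.
Rankings sort descending (higher index = better multitarget profile),
ties broken by compound id, rank 1 best.

## Affinity landscape

The three-target landscape interpolates one target's mean score over
the plane of the other two, using piecewise-linear interpolation on a
Delaunay triangulation of the compound scatter (scipy's
LinearNDInterpolator). Linear gridding was chosen because it is
reproducible and bounded — interpolated values never leave the range of
the contributing triangle's vertices — where spline or kriging surfaces
would invent extrema. Cells outside the convex hull are masked, never
extrapolated. At least three non-collinear compounds with all three
scores are required. Axes are emitted in ascending score order; the
plotting layer may invert them so better (more negative) scores appear
bottom-left.

## Structural metrics

Structures and trajectories are PDB files, multi-model via MODEL/ENDMDL
(frames must agree in atom count and identity; the frame interval `dt`
defaults to 100 ps). ATOM and HETATM records are kept; alternate
locations other than blank or 'A' are skipped; hydrogens are excluded
from distance metrics by element.

* **In-place RMSD** pairs atoms by file order after applying one
  selection to both frames and applies no superposition — the docking
  convention for comparing a redocked pose against crystal coordinates
  (the usual validity threshold being 2 Å). No bond-graph symmetry
  correction is applied, a documented limitation for ligands with
  topologically equivalent atoms.
* **Kabsch superposition** returns the proper rotation (det +1;
  reflections excluded, so a mirrored chiral set cannot align to zero),
  translation, and minimal RMSD, computed via the SVD-based solver in
  scipy. Collinear or sub-3-point inputs are rejected as degenerate.
* **Backbone-RMSD profile**: per frame, superpose atoms named N, CA, C
  (O excluded) onto a reference frame and record the minimal RMSD. The
  profile is invariant to a global rigid transform of the trajectory.
* **Distance profile**: per frame, either the minimum heavy-atom
  distance between two selections (default — appropriate when the
  interacting atoms are known only at residue resolution, e.g. a ligand
  approaching a catalytic serine) or one named atom pair for exact
  reproduction attempts.
* **Summaries** (mean/min/max/first/last) are taken over frames at or
  after a burn-in time.

Atom selections are conjunctive filters on chain, residue number,
residue name and atom names, with a compact CLI syntax
(`chain:A,resseq:238,resname:SER,names:OG`).

## Synthetic data

The generators define the conditions under which everything downstream
is tested; their defaults are fixed, not tuning knobs.

**Score tables** emulate a virtual screen of ~100 compounds against four
targets with two structures each. Per-target compound means are drawn
normal with mean −120 and spread 25 (the published top-10 window spans
roughly −137 to −215, and a screening library's bulk sits well above its
top-10), clipped negative; per-structure replicates add Gaussian scatter
of 2. A configurable number of planted multitarget binders (default 3)
are placed at each target's background minimum plus k × 2% of the score
range (k = 1, 2, …) — near-best on every target, never exactly tied.
Planted binders take the top vMTi ranks in ≥95% of seeds, a calibration
the test suite checks over 200 seeds.

**Trajectories** emulate an MD snapshot series: a random protein-like
backbone (N, CA, C per residue; the last residue is a serine carrying an
OG atom) plus a small ligand, moved rigidly (default 2°/frame rotation,
0.1 Å/frame drift) and jittered with isotropic Gaussian coordinate noise.
An optional planted approach pins one ligand-atom/serine-atom distance
to a linear ramp (default 4.8 → 3.0 Å, the ramp optionally confined to
an initial fraction of frames, mimicking a ligand settling early and
then holding) before noise is added.

What the generators do **not** emulate: correlated score errors between
related compounds, chemotype clustering, pose geometry, solvent or
thermostat artifacts, or anything force-field-like. Passing tests
therefore demonstrate correctness of the arithmetic and its invariances
under the stated noise models, not predictive validity of docking
scores on real screens.

Stochastic oracles in the suite run at fixed seeds. Their tolerances are
derived from the noise model: RMSD of σ-jittered coordinates against a
clean reference has expectation √3·σ (checked within 10%); the mean
absolute deviation of a noisy pair distance from its planted ramp has
expectation 2σ/√π, since both endpoints jitter (within 15%); the
recovered post-ramp mean distance is held to 3σ/√n_frames, a roughly
two-standard-error band for that estimator, which is why the seed is
fixed rather than free.

## Reproducing the published tables

The packaged fixture transcribes the published per-structure scores of
the top-ranked compounds. Recomputing from it: ensemble means match
every printed average within ±0.05 (three printed averages differ from
the recomputed mean by exactly 0.05 — e.g. −206.1 printed vs −206.15
recomputed — indicating the source carried more decimals than it
printed); the per-target references are EcR −210.6 (compound 88), PPO
−161.187 (86), DmAChE −212.9 (90), hAChE −212.65 (90); and the
two-decimal vMTi/wMTi of the three compounds printed for all four
targets are (2.86, 0.60), (2.72, 0.56) and (2.58, 0.54), with SR 1.17,
1.17 and 1.00 for compounds 88, 87 and 90. The acceptance script
recomputes exactly this pipeline. Problem sizes throughout the suite
(10–50 compounds, 30–300 frames, 200-seed Monte-Carlo loops) keep any
single test well under a minute while leaving the statistical checks
meaningfully powered.

## Known limitations

* No ligand-topology symmetry correction in RMSD.
* Only multi-model PDB trajectories are read (DCD/XTC are extension
  points); fixed-column PDB limits coordinates to 0.001 Å precision.
* The index presumes negative-is-better scoring; positive-is-better
  scoring functions would need sign flipping at ingest.
* Reference scores are relative to the loaded table: rankings from
  different score-table subsets are not directly comparable.
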