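# mtindex

Multitarget prioritization for docking-based virtual screening, built
around an insecticide-discovery use case: screening plant secondary
metabolites (e.g. phenylethanoid glycosides from *Calceolaria*) against
three insect targets — the ecdysone receptor (EcR), prophenoloxidase
(PPO) and *Drosophila melanogaster* acetylcholinesterase (DmAChE) — while
penalizing predicted affinity for the human off-target hAChE.

## The indices

Docking scores here follow the MolDock convention: dimensionless, more
negative = better predicted affinity. For a compound *i* and target *t*,
MD<sub>i</sub>(t) is the mean score over that target's receptor
structures (ensemble docking), and MD<sub>r</sub>(t) is the best (most
negative) mean score of any compound for *t* — the reference ligand.

- **Virtual multitarget index**
  vMTi = Σ<sub>t ∈ insect targets</sub> MD<sub>i</sub>(t) / MD<sub>r</sub>(t).
  Each ratio lies in (0, 1] when all scores are negative, so vMTi → 3
  flags a compound near-best on all three insect targets, while a
  single-target binder saturates near 1 plus small change. This is what
  a plain score average cannot distinguish.
- **Weighed multitarget index**
  wMTi = Σ<sub>t</sub> n<sub>t</sub> · MD<sub>i</sub>(t) / MD<sub>r</sub>(t),
  with a desirability coefficient n<sub>t</sub> per target. Shipped
  defaults: +0.3 for EcR, PPO, DmAChE and −0.3 for hAChE, so predicted
  binding to the human enzyme subtracts from the score.
- **Selectivity ratio** SR = MD<sub>i</sub>(DmAChE) / MD<sub>i</sub>(hAChE);
  SR > 1 suggests preference for the insect enzyme.

The package also builds the three-target affinity landscape (one
target's score interpolated over the plane of the other two — multitarget
binders sit in the low-score valley) and the structural metrics used
around such a study: in-place heavy-atom RMSD for redocking validation,
Kabsch superposition, backbone-RMSD and ligand–residue distance time
profiles for MD snapshot series, plus seeded synthetic generators for
score tables and trajectories.

## Worked example

The package ships the published per-structure docking scores of the
top-ranked compounds as `fixtures/paper_tables.csv` (`--scores builtin`):

```sh
mtindex index --scores builtin --out out/
```

prints

```
References (best mean score per target):
  EcR: compound 88 (MDr = -210.6)
  PPO: compound 86 (MDr = -161.187)
  DmAChE: compound 90 (MDr = -212.9)
  hAChE: compound 90 (MDr = -212.65)
Excluded (missing a required target score): 90, 89, 92, 87, 91, 68, 45, 110, 109, 108, 111, 104, 107, 44, 43
```

and writes `out/index.csv`:

```
compound_id,vmti,wmti,rank_vmti,rank_wmti,sr_DmAChE_hAChE
88,2.86,0.6,1,1,1.17
86,2.72,0.56,2,2,1.04
93,2.58,0.54,3,3,1.16
```

Reading: Calceolarioside C (compound 88) is within 2% of the best score
on every insect target (vMTi = 2.86 of a possible 3) and 1.17× more
selective for the fly enzyme than the human one, so it ranks first on
both indices. Compounds listed as excluded carry scores for only some
targets in the published top-10 tables, so their three-target index is
undefined (pass `--strict` to make that an error, or use the library's
`impute_missing` option). Other subcommands: `contour` (landscape grid),
`rmsd` (pose validation), `traj` (profile a multi-model PDB trajectory),
`simulate` (synthetic fixtures).

As a library:

```python
import mtindex as m

table = m.load_published_scores()
index = m.build_index_table(table)        # aggregate -> references -> indices
print(index.rows[["vmti", "wmti"]].round(2))
```

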