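# morphoconflict

Statistical dissection of character-level support and conflict in discrete
morphological phylogenetics.

When two research groups score the same taxa for the same anatomical
characters and reach incompatible trees — as happened for the deepest
branches of the dinosaur tree, where the competing resolutions Saurischia
(S), Ornithischiformes (Of) and Ornithoscelida (Os) of the
Theropoda/Sauropodomorpha/Ornithischia branch are each supported by some
version of the same matrix — the interesting question is not which point
estimate to prefer but *how the support is distributed across characters*,
and whether the data can discriminate between the hypotheses at all.
`morphoconflict` implements a full maximum-likelihood protocol for that
question, aimed at morphological systematists and anyone auditing a
published character matrix.

## What it computes

**Model.** Characters evolve under the Mk model: a k-state Markov process
(k = 2–5) with equal exchange rates and uniform stationary frequencies;
ordered (additive) characters exchange only between neighboring states.
Characters are partitioned by (ordering, number of observed states), share
one set of branch lengths up to per-partition rate multipliers, carry
unlinked discrete-gamma rate heterogeneity, and are corrected for
ascertainment bias by conditioning on variability (constant characters are
never collected, so each likelihood is divided by 1 − Σ_s P(constant
pattern s)).

**Protocol**, mirroring phylogenomic conflict analyses:

1. *Tree search*: multi-start NNI hill-climbing ML search from
   random-addition parsimony starting trees, with optional monophyly
   constraints; nonparametric bootstrap for clade support.
2. *Topology tests* on per-character log-likelihoods via RELL resampling:
   bootstrap proportions, Kishino–Hasegawa (KH), Shimodaira–Hasegawa (SH)
   and weighted SH, expected likelihood weights (ELW), and the
   approximately unbiased (AU) test; the *plausible set* keeps every tree
   no test rejects.
3. *Difficulty score*: from N independent searches, the unweighted mean of
   five [0, 1] terms — mean pairwise normalized Robinson–Foulds distance
   over all trees and over the plausible subset, the two unique-topology
   fractions, and one minus the plausible fraction.
4. *Signal decomposition*: for character i and hypothesis pair (A, B),
   ΔCLS(A,B)_i = lnL(C_i|A) − lnL(C_i|B); the phylogenetic signal PS_i is
   the mean of the three |ΔCLS|. Favored-hypothesis counts are tested for
   uniformity with an exact multinomial test; outliers (> mean + 3 sd,
   one-sided) and "strong" characters (best-vs-second gap > 0.5) are
   flagged.
5. *Perturbation experiments*: re-searching after removing top-PS or
   outlier characters, and a one-character-at-a-time rescoring scan between
   two rival matrices that finds single codings able to flip the tree.
6. *Synthetic data*: a generator producing matrices with a known mixture of
   characters supporting each resolution, realistic missing-data structure,
   and a ground-truth manifest — so the whole stack is testable end to end.

## Worked example

```python
import morphoconflict as mc

cfg = mc.SimulationConfig(
    n_taxa=12, n_chars=150, conflict_weights=(0.34, 0.33, 0.33),
    state_count_weights=(0.8, 0.2, 0.0, 0.0), ordered_fraction=0.0,
    missing_fraction=0.4, alpha=1.0, focal_branch_length=0.02, seed=1,
)
matrix, truth = mc.simulate_matrix(cfg)
model = mc.PartitionedMkModel(matrix)

fits = [model.fit(mc.tree_from_newick(truth.hypothesis_trees[h]), label=h)
        for h in ("S", "Of", "Os")]
print(fits[0].summary())

table = mc.SiteLikelihoodTable.from_results(fits)
print(mc.run_tests(table, B=10000, seed=1).summary())

rep = mc.signal_report(table)
counts = mc.favored_counts(rep)
print("favored counts:", {k: int(v) for k, v in counts.items()})
print("multinomial p =", round(mc.multinomial_uniformity(
    [counts['S'], counts['Of'], counts['Os']]), 3))
print("mean PS =", round(rep.ps.mean(), 3), " max PS =", round(rep.ps.max(), 3))
```

prints

```
Partitioned Mk model fit
========================================================
Taxa: 12   Characters (variable): 138
log-likelihood: -716.724124
tree length: 2.3665
converged: True (sweeps: 14)
--------------------------------------------------------
partition              n_chars   rate_mult     alpha
unordered k=2              127      1.0000     4.175
unordered k=3               11      2.5331   100.000
========================================================

Topology tests (alpha = 0.05)
------------------------------------------------------------------------------
           lnL  bp_RELL   p_KH   p_SH  p_wSH   p_AU  c_ELW  plausible
tree
Os   -715.4306   0.5749 0.5955 1.0000 0.6828 0.6848 0.5064       True
Of   -716.0558   0.3852 0.4045 0.4776 0.5241 0.4077 0.3534       True
S    -716.7241   0.0399 0.2295 0.3810 0.4324 0.1229 0.1402       True

favored counts: {'S': 27, 'Of': 49, 'Os': 62, 'tie': 0}
multinomial p = 0.001
mean PS = 0.087  max PS = 0.666
```

Reading this: the matrix was built with equal thirds of characters
supporting each resolution and a very short focal branch, and the analysis
recovers exactly the signature of genuine conflict — the three hypotheses
differ by ~1 log-likelihood unit, *none* is rejected by any test (all
plausible), and the per-character decomposition shows every hypothesis
favored by a sizable block of characters. The exact multinomial p here is
small because the three optimized trees differ slightly in branch lengths,
which tilts the argmax of many near-tie characters — the same caveat that
motivates looking at ΔCLS magnitudes rather than bare counts.

The same analyses run from the shell:

```bash
morphoconflict simulate --taxa 12 --chars 150 --conflict 0.34,0.33,0.33 --seed 1 --out m.nex
morphoconflict search --matrix m.nex --nstarts 10 --seed 42 --out search_out
morphoconflict run --config pipeline.yaml
```

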