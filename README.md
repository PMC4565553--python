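# cardevol

Molecular-evolution and binding-kinetics analysis for CARD-domain families.

The RIG-like receptors (RIG-I, MDA5, LGP2) sense viral RNA in the cytoplasm
and signal through direct contacts between their CARD (caspase activation
and recruitment) domains and the single CARD of IPS1/MAVS.  Reconstructing
how that interaction arose requires a chain of analyses that each need
careful error control: ancestral sequence reconstruction that is honest
about phylogenetic uncertainty, selection tests whose false-positive
behaviour has been measured, clustering methods that work at deep
divergence where trees are unreliable, and binding-constant estimation from
kinetics traces.  `cardevol` packages that chain as a tested, reusable
pipeline for anyone studying the diversification of protein-interaction
domain families.

## What it computes

- **Ancestral reconstruction with topology uncertainty** — empirical-Bayes
  marginal reconstruction under LG+F+Γ on each topology of a weighted tree
  set, integrated per clade with the trees' posterior weights
  (`P(state | data) ∝ Σ_c π · up_c · down_c`, averaged over trees
  containing the clade); Fitch-parsimony indel states; confidence
  summaries (fraction of sites with posterior > 0.95/0.90/0.80, ambiguous
  sites, biochemical-class agreement).
- **Calibration by simulation** — per-node ancestral-reconstruction error
  rates (strict and biochemical-class) from data simulated under the
  fitted model, and the false-positive rate of the branch-site test under
  neutral / sites / branch-released simulation regimes.
- **Branch-site test of positive selection** — codon model A
  (ω₂ ≥ 1 on one foreground branch) vs its null (ω₂ = 1), statistic
  2ΔlnL against χ²(1), Bonferroni-corrected across tested branches.
- **Subfamily clustering** — per-group profile HMMs, symmetrized
  Kullback–Leibler distances between match emissions, neighbor joining;
  and an all-vs-all Smith–Waterman similarity network with
  Karlin–Altschul e-values (edges kept at e ≤ 10⁻³).
- **Duplication/loss rooting** — every candidate root of an unrooted gene
  tree scored by LCA reconciliation against a species tree.
- **Gene-conversion screen** — maximal pair-agreement tracts over
  polymorphic columns with permutation p-values.
- **Binding kinetics** — blank correction, steady-state (last 500
  association samples) and initial-rate extraction, one-site fits
  `R = Rmax·C/(Kd + C)` under two replicate-averaging schemes, pKd/pKm,
  Welch comparisons.
- **Synthetic data generators** for all of the above (trees, LG+Γ protein
  alignments with recorded ancestral truth, codon alignments under ω
  regimes, 1:1 Langmuir binding traces).

See `docs/methods.md` for the models, conventions and limitations.

## Worked example: binding constants from synthetic traces

```python
import cardevol as ce
from cardevol.simulate import KineticsSimSpec
from cardevol.kinetics import blank_correct, estimate_binding

spec = KineticsSimSpec(Kd_true=3e-8, noise_sd=0.02, seed=11)
traces = blank_correct(ce.simulate_kinetics(spec))
for scheme in ("per_replicate", "averaged"):
    fit = estimate_binding(traces, scheme, responses=("steady_state",))["Kd"]
    print(scheme, f"Kd = {fit.K:.3e} M, pKd = {fit.pK:.3f}, r^2 = {fit.r_squared:.4f}")
```

```
per_replicate Kd = 3.017e-08 M, pKd = 7.520, r^2 = 1.0000
averaged      Kd = 3.017e-08 M, pKd = 7.520, r^2 = 1.0000
```

Three simulated replicates at seven concentrations, generated with a true
Kd of 3×10⁻⁸ M and 2% noise, recover the constant within 1% under both
schemes (per-replicate estimates 3.01–3.03 × 10⁻⁸ M); r² = 1.00 clears the
0.91 quality flag.

## Worked example: an ancestral subfamily sequence

```python
import cardevol as ce
from cardevol.asr import confidence_summary

aln, tree, groups = ce.card_family_fixture(seed=7)   # 5 groups x 10 taxa, 95 aa
model = ce.lg_model(ce.empirical_frequencies(aln.records), alpha=1.0, ncat=4)
fit = ce.optimize(aln, tree, model, free_params=("branch_lengths", "alpha"))
recs = ce.marginal_reconstruct(aln, fit.tree, fit.model)
anc = recs[frozenset(groups["G1"])]                  # ancestor of subfamily G1
summary = confidence_summary({anc.clade: anc})["pooled"]
print(round(fit.model.alpha, 3), round(summary["above_threshold"][0.95], 3))
print(anc.map_sequence()[:30])
```

```
0.775 0.726
RRLTAGFCFGNPFHLYAQWTLEHVKKNEVH
```

On the bundled synthetic five-subfamily fixture, the fitted gamma shape is
0.78 and 72.6% of the G1 ancestor's sites are reconstructed with posterior
probability above 0.95 (6 of 95 sites carry an alternative residue above
posterior 0.3).

## Command line

`cardevol` exposes each stage as a subcommand (`simdata`, `fit`, `asr`,
`calibrate-asr`, `calibrate-fpr`, `selection`, `geneconv`, `profiles`,
`network`, `kinetics`) plus `run`, which executes a staged pipeline from a
JSON config with per-stage seeds, a checksum manifest and a log.  Try:

```bash
cardevol simdata --kind card-family --seed 1 --out demo/
cardevol network --alignment demo/card_family.fasta \
    --groups demo/card_groups.tsv --out demo/net/
```

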