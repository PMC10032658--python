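# coevoscan

Phylogenetic co-evolution analysis of a candidate gene's coding and
regulatory sequences with continuous organismal traits — built around the
question of whether the evolution of a neurodevelopmental gene (its protein
substitution rate, the activity of its cis-regulatory elements, and the
proliferative activity of its protein orthologues) tracks the evolution of
brain size and cortical folding (gyrification) across mammals.

The package is aimed at molecular evolutionists and comparative genomicists
who want a tested, reusable implementation of this analysis pattern:

1. **Rate–trait co-evolution.** The dN/dS ratio ω of a focal gene is related
   to log-transformed traits (brain size, gyrification index GI, body mass)
   under a multivariate Brownian-motion model on a species phylogeny.
   A fast estimator based on Felsenstein's phylogenetically independent
   contrasts (PIC) gives the marginal correlation between rate and trait;
   partial correlations from the precision matrix separate direct linkage
   from confounding through correlated traits (body mass as a proxy for
   effective population size).
2. **Control-gene ranking.** Because variation in the efficacy of selection
   affects *all* genes, the focal gene's correlation is ranked against a
   cohort of control genes selected to have comparable statistical power
   (single coding exon, similar CDS length, complete orthologue sets,
   bounded length ratios, no dS tree-length outliers). The report is a
   percentile: "more correlated than X% of control proteins".
3. **Tiled MPRA quantification.** Regulatory elements are assayed as
   overlapping 94-bp tiles (40-bp step) in a massively parallel reporter
   assay. Per-tile activity is

   `a_i = median(CPM_i, RNA replicates) / median(CPM_i, plasmid replicates)`

   and the full-element activity is reconstructed coverage-sensitively:
   for every base, the mean per-base activity `a_i / l_i` over the detected
   tiles covering it, summed over bases —

   `a_r = Σ_b mean_{i ∋ b} (a_i / l_i)`.

   A permutation null (resampling the activities of all other elements)
   calibrates the element–trait PGLS association.
4. **Proliferation-rate modelling.** Cell-assay counts (Ki67+ among GFP+
   transfected neural stem cells) are fit by weighted binomial logistic
   regression with batch selection by likelihood-ratio test; per-condition
   rates are back-calculated by the inverse logit and linked to brain
   phenotypes by phylogenetic generalized least squares (PGLS) under a
   Brownian covariance, with likelihood-ratio tests and residual R².

Every input can be simulated by the `synthdata` module with the statistical
structure the analyses assume, so the whole pipeline is testable end-to-end
without any external downloads.

## Worked example

Simulate a 30-species phylogeny on which log ω co-evolves with log brain
size (diffusion correlation 0.8), estimate the correlation by independent
contrasts, and rank the focal gene against 124 uncorrelated control genes:

```python
import numpy as np
from coevoscan import synthdata, phylocomp

tree = synthdata.simulate_tree(30, seed=1)
scenario = synthdata.EvolScenario.from_correlations(
    variances=[0.04, 0.25, 0.04, 0.36],
    corr_omega_brain=0.8, corr_omega_gi=0.48, corr_omega_body=0.56,
    corr_brain_gi=0.6, corr_brain_body=0.7, corr_gi_body=0.4,
    seed=2,
)
sim = synthdata.simulate_traits_and_rates(tree, scenario)
r, p = phylocomp.pic_correlation(
    tree, sim.traits["log_omega"].to_dict(), sim.traits["log_brain"].to_dict()
)
print(f"PIC correlation of log omega with log brain size: r = {r:.3f} (p = {p:.2g})")

controls = []
for i in range(124):
    logw, _ = synthdata.simulate_rate_on_traits(
        tree, sim.node_states, trait_dim=1, trait_var=0.25, rho=0.0, seed=100 + i
    )
    rc, _ = phylocomp.pic_correlation(
        tree, logw.to_dict(), sim.traits["log_brain"].to_dict()
    )
    controls.append(
        phylocomp.GeneEvolSummary(gene_id=f"ctrl{i}", marginal_r={"brain": rc})
    )
focal = phylocomp.GeneEvolSummary(gene_id="focal", marginal_r={"brain": r})
pct = phylocomp.rank_focal(controls, focal, "brain")
print(f"focal gene percentile among 124 controls: {pct:.1f}%")
```

Output:

```
PIC correlation of log omega with log brain size: r = 0.800 (p = 1.1e-07)
focal gene percentile among 124 controls: 0.8%
```

The contrast correlation recovers the simulated diffusion correlation, and
the focal gene outranks every control (percentile 1/125 = 0.8%), exactly the
situation in which a gene-specific rate–trait link stands out from
genome-wide effects of selection efficacy.

An end-to-end study — simulation, MPRA quantification, permutation null,
proliferation model and ranking — runs from the command line:

```bash
coevoscan run --out results/ --seed 1
```

which writes `results/results.json` plus trait and gene-summary tables.
Subcommands (`coevoscan mpra quantify`, `coevoscan pgls`,
`coevoscan controls dnds`, `coevoscan prolif fit`, …) expose the individual
stages on TSV/FASTQ/newick inputs; see `coevoscan --help`.

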