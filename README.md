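# aldmix

Local and global ancestry inference in admixed samples from **dense,
phased** marker data, with the admixture-mapping (MALD) statistics
needed to take a study from quality control to disease-gene mapping.

## The problem

When two populations mix, each admixed genome becomes a mosaic of
long chromosomal segments inherited from the founding populations.
The admixture linkage disequilibrium (ALD) spanning these segments
decays with each generation but still extends over many centimorgans
— far beyond the ~0.1 cM reach of ancestral LD — so testing *local
ancestry* against a phenotype needs orders of magnitude fewer
comparisons than a standard GWAS for traits whose risk differs
between the founding populations.  Classical admixture HMMs require
sparse markers because ancestral LD between nearby markers biases
them; aldmix models that LD indirectly, through principal components
of haplotype windows from modern surrogate panels, and so works on
dense data.

## The model

The genome is tiled into fixed-width windows (default 0.1 cM).  The
hidden state of window *j* on a haplotype is its ancestral population
*g* ∈ {1..K}; the chain prior combines the haplotype's global
ancestry *A* with state persistence,

    P(g_j = k) = A_k·P(r_j) + γ_{j−1,k}·(1 − P(r_j)),
    P(r_j)     = 1 − ((1 + e^{−2d_j/100})/2)^λ,

where *d_j* is the inter-window distance in cM and λ the number of
generations since admixture.  Emissions blend the window's
allele-frequency likelihood with a logistic principal-component
regression (PCR) of ancestry on the surrounding ±1 cM of haplotype,
weighted by the probability 1 − e^{−λw/100} that an admixture-era
crossover has disrupted the support haplotype.  Posterior fields γ
come from a forward–backward pass; a Metropolis-within-Gibbs sampler
updates every parameter (global ancestry A and its Dirichlet
concentration ω, λ and its Gamma hyperparameters, allele frequencies
p with Beta priors τP, PCR coefficients β with normal priors, and the
surrogate-fit concentration τ).  A low posterior τ (< 100, strongly
< 50) warns that the surrogate panels fit the admixed sample poorly.

Association models over the inferred diploid ancestry dosage:
case-only (global ∼ local), case-control/quantitative
(link(Y) ∼ local + global + covariates) and per-marker fine mapping
(link(Y) ∼ genotype + local + global + covariates).

See `docs/methods.md` for the full model, priors, numerical choices
and limitations.

## Worked example

Everything below is synthetic and self-contained — the package ships
a simulator that generates diverged surrogate panels with realistic
within-population LD and admixed chromosomes with known ancestry at
every marker.

```python
import numpy as np
from aldmix import (SyntheticPanelSpec, simulate_panels, simulate_admixed,
                    build_windows, compute_priors, run_mcmc, McmcConfig,
                    truth_window_labels, window_accuracy)

spec = SyntheticPanelSpec(n_hap=80, n_markers=1000, divergence=0.15,
                          length_cm=50.0, seed=7)
panels, _, _ = simulate_panels(spec)
cm = spec.positions_cm()
chroms = simulate_admixed(panels, cm, n_chrom=60, seed=8)   # 30 individuals
X = np.vstack([c.alleles for c in chroms])

windows = build_windows(np.repeat("1", cm.size), cm, window_cm=0.1)
prior = compute_priors(panels, windows)

res = run_mcmc(X, prior, McmcConfig(n_burn=50, n_keep=100),
               rng=np.random.default_rng(9))

truth = truth_window_labels(chroms, windows)
print(f"window-level accuracy:   {window_accuracy(res.field.gamma, truth):.3f}")
```

Output:

```
windows analyzed:        501
window-level accuracy:   0.989
mean global ancestry:    0.827 (truth 0.807)
mean generations (lam):  5.97 (truth 5.68)
posterior tau:           [2382 2672]
```

98.9% of (haplotype, window) ancestry calls match the simulation
truth; the posterior means of global ancestry and of the number of
generations since admixture track their simulated values; the high τ
says the surrogate panels describe the admixed sample well (values
below 50–100 would flag a panel mismatch or allele flips).

## Command line

The same pipeline as a shell workflow:

```bash
aldmix simulate --seed 1 --out-dir sim/
aldmix prepare-priors --panel sim/panel0.vcf --panel sim/panel1.vcf \
       --map sim/genetic_map.txt --out prior.npz
aldmix infer --data sim/admixed.vcf --priors prior.npz \
       --map sim/genetic_map.txt --out-dir inference/
aldmix qc --data sim/admixed.vcf --panel sim/panel0.vcf \
       --panel sim/panel1.vcf --out qc.tsv
aldmix associate --ancestry inference/ancestry.tsv \
       --phenotype pheno.tsv --model logistic --out scan.tsv
aldmix diagnose --trace inference/trace_chain0.tsv --n-burn 100 --out diag.tsv
```

Inputs: phased VCF (or Oxford HAPS/SAMPLE) plus a whitespace genetic
map (chromosome, [id], bp, cM).  Every run writes a JSON manifest
with the package version, seed and configuration hash.

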