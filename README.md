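# rindqtl

Genetic dissection and genomic prediction of maize stalk strength, measured as
**rind penetrometer resistance** (RPR, kg/mm²), in biparental recombinant
inbred line (RIL) populations.

Stalk lodging is a major source of yield loss in maize, and RPR — the force
per unit area needed to puncture the stalk rind — is the standard proxy for
stalk strength. Dissecting its genetics requires a full pipeline: trial
statistics, marker QC, linkage-map construction, QTL mapping, and genomic
selection. Field datasets of this kind are rarely public, so `rindqtl` pairs
every analysis stage with a synthetic-data generator that emulates two
selfing-RIL populations (hundreds of lines, 10 chromosomes, seven measurement
stages from the tenth-leaf stage V10 through 50 days after silking, 2–3
environments × 2 replicates) with *known* ground truth, making every estimator
verifiable by closed-form oracles and parameter recovery.

## What it computes

**Phenotype statistics** (`rindqtl.pheno`). Balanced two-way ANOVA
`y_ijk = μ + g_i + e_j + ge_ij + r_k(j) + ε_ijk` with expected-mean-square
variance components; entry-mean broad-sense heritability

    H² = σ²_g / (σ²_g + σ²_ge/e + σ²_ε/(r·e))

per-line BLUEs across environments by mixed-model GLS; stage standardization,
Euclidean distances and hierarchical clustering; phenotypic correlations
`r_p = cov_p(A,B)/√(v_pA·v_pB)` and genetic correlations
`r_g = cov_g(A,B)/√(v_gA·v_gB)` from method-of-moments mean cross-products.

**Genotype QC and linkage maps** (`rindqtl.mapqc`). Missing-rate (>0.20) and
MAF (<0.05) filters; χ² tests of 1:1 segregation (df=1, markers with P<0.05
removed as distorted); sliding-window bin calling to absorb genotyping errors;
and Kosambi linkage maps, `d = 25·ln((1+2r)/(1−2r))` cM, with the inverse RIL
expansion `r = R/(2(1−R))` applied to observed recombinant fractions.

**QTL mapping** (`rindqtl.qtl`). Regression-based composite interval mapping
(Haley–Knott) on a pseudo-marker grid with forward-selected cofactors and an
exclusion window, `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`; genome-wide permutation
thresholds; LOD-drop support intervals with additive effects (half the
homozygote difference, signed by parental origin) and PVE; and pleiotropic-QTL
integration by transitive overlap of physical support intervals.

**Genomic selection** (`rindqtl.gs`). GBLUP in four flavors — UV (plain
`y = 1μ + u + ε` with VanRaden's `G = ZZ′/2Σp(1−p)`), FIXED (QTL-peak markers
as fixed effects, G rebuilt from the remaining markers), and ME / MS
multivariate models adding `v ~ N(0, G_v σ²_v)` with the auxiliary-phenotype
kernel `G_v = n·M_vM_v′/trace(M_vM_v′)` built from other environments or
stages — fitted by Gibbs sampling (default 10,000 iterations, 5,000 burn-in)
with a deterministic mixed-model-equation solver as oracle, and evaluated by
replicated 5-fold cross-validation (`r_MP` = correlation of test-fold GEBVs
with observed phenotypes).

## Worked example

```python
import numpy as np
from rindqtl import simulate as sim, pheno, qtl
from rindqtl.mapqc import MarkerMatrix

cfg = sim.SimConfig(
    n_lines=200,
    chromosomes=(sim.ChromosomeSpec(100.0, 100_000_000, 51),) * 2,
    qtl=(sim.QTLSpec(1, 50.0, tuple([0.3] * 7)),),  # +0.3 kg/mm² per allele
    seed=5,
)
gmap = sim.simulate_genetic_map(cfg)
pop, arch = sim.simulate_ril_population(gmap, cfg.n_lines, seed=5)
table = sim.simulate_phenotypes(pop, arch, cfg)

vc = pheno.anova_components(table[table.stage == "AS30"].drop(columns="stage"))
print(round(pheno.broad_sense_heritability(vc), 3))     # 0.850

mm = MarkerMatrix(pop.geno, gmap[["marker", "chrom", "pos_bp"]])
grid = qtl.genotype_probabilities(gmap, mm, step_cM=1.0)
y = table[table.stage == "AS30"].groupby("line")["value"].mean().to_numpy()
scan = qtl.cim_scan(y, grid)
peak = scan.positions.iloc[int(np.argmax(scan.lod))]
print(round(scan.lod.max(), 1), peak["chrom"], peak["pos_cM"])  # 20.3 1 51.0
```

The heritability estimate (0.850) matches the configured stage target; the
composite-interval scan peaks at LOD 20.3 on chromosome 1 at 51 cM, one
centimorgan from the simulated QTL, and the fitted additive effect (0.348)
recovers the generative 0.3 kg/mm² within sampling error.

The same pipeline is scriptable from the shell:

```bash
rindqtl simulate --config sim.yaml --seed 1 --out run/
rindqtl pheno --phenotypes run/phenotypes.tsv --out run/pheno
rindqtl qc --genotypes run/genotypes.tsv --map run/map.tsv --out run/qc
rindqtl map --genotypes run/qc/genotypes_qc.tsv --map run/qc/map_qc.tsv --out run/lmap
rindqtl scan --genotypes run/qc/genotypes_qc.tsv \
    --linkage-map run/lmap/linkage_map.tsv \
    --phenotypes run/phenotypes.tsv --stage AS30 --out run/scan
```

Every subcommand writes tab-separated outputs plus a JSON run manifest
recording the seed, the parameter defaults in force, and input digests.

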