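# popsel

Analysis toolkit for two-population genome polymorphism data: joint
site-frequency spectra (construction, hypergeometric projection, folding,
residual comparison), expected spectra under an isolation-with-migration
demography with genic selection (a finite-volume diffusion solver validated
against an exact Wright-Fisher transition-matrix oracle), mixture
distribution-of-fitness-effects (DFE) inference with a lethal point mass,
McDonald-Kreitman statistics with a Bayesian Poisson random-effects gene
classifier, and identity-by-state / mtDNA summaries.  A synthetic-data
module generates every input the pipeline consumes, so the whole analysis
is testable offline.

## Layout

| module | contents |
|---|---|
| `popsel.sfs` | `Spectrum`, `GenotypeMatrix`, build/project/fold/rescale/residual |
| `popsel.demography` | `DemographicModel`, selection grid, diffusion solver, Wright-Fisher oracle, per-gamma spectra cache |
| `popsel.dfe` | DFE families (point+lethal, exponential+lethal, normal+lethal, gamma), Poisson-likelihood fitting, class-mass tables, bootstrap CIs |
| `popsel.mk` | per-site rates, NS/S ratios, Yates chi-square, gene filter, random-effects classifier |
| `popsel.summaries` | IBS allele-sharing matrices, heteroplasmy filter, SNP density |
| `popsel.simulate` | seeded generators: SFS, genotype matrices, MK tables with truth labels, mtDNA haplotypes |
| `popsel.io` / `popsel.pipeline` / `popsel.cli` | VCF/TSV/YAML I/O, orchestration, CLI |

## CLI

All stages are subcommands sharing a YAML config schema (any flag overrides
its config key):

```sh
popsel simulate --seed 1 --out sim/                # synthetic VCF + MK tables
popsel sfs --vcf sim/genotypes.vcf --pop-map sim/pop_map.tsv --out sfs.txt
popsel fit-dfe --spectrum sfs.txt --family point_lethal --seed 1 --out fit.json
popsel mk --tables sim/mk_tables.tsv --out mk.json
popsel classify --tables sim/mk_tables.tsv --seed 1 --out genes.tsv
popsel ibs --vcf sim/genotypes.vcf --pop-map sim/pop_map.tsv --out ibs.tsv
popsel run --config config.yaml --seed 1 --out results/
```

`popsel run` executes build -> project -> fold -> cache -> DFE fits ->
MK statistics -> gene classification -> IBS and emits table/figure data
files plus a structured run log with input hashes and seeds.

## Conventions

Selection is genic (h = 1/2) with gamma = 2*N_anc*s; time is measured in
units of 2*N_anc generations; migration rates are 2*N_anc times the
per-generation fraction; theta is the unit mutation influx (neutral
equilibrium spectrum theta/i).  The default non-synonymous influx is
2.5x the synonymous one.  The bundled demographic configuration is an
illustrative two-population scenario (6x expansion in population 2, modest
decline in population 1, recent split) — it is not a fitted parameter set.
Spectra are folded for all likelihood work; the lethal DFE class (gamma
below -2000) contributes no polymorphism.
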