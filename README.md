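# culturekin

Quantitative-genetics tooling for partitioning the inherited variance of a
behavioral trait into **genetic** and **cultural** (socially transmitted)
components, for researchers running pedigree-based animal models on
populations where parents both transmit genes and tutor their offspring —
song dialects in hole-nesting birds, foraging habits, mating preferences.

In such populations the genetic genealogy and the "cultural genealogy" of
who-reared-whom coincide, so the classic animal model attributes all
vertical resemblance to genes. `culturekin` implements the dual-pedigree
remedy: an extended animal model

    y_i = mu + a_i + c_i + m_dam(i) + cb_brood(i) + e_i,
    sigma2_P = sigma2_A + sigma2_C + sigma2_M + sigma2_CB + sigma2_ENVT
               + sigma2_R

where `a ~ N(0, sigma2_A A)` with `A_ij = 2 theta_ij` the additive genetic
relationship matrix from the pedigree, and `c ~ N(0, sigma2_C C)` with `C`
a cultural relationship matrix built from rearing links, culture identity
or social contacts. Variance components are estimated by REML;
`h2 = sigma2_A / sigma2_P` is the narrow-sense heritability and
`sigma2_C / sigma2_P` the cultural component of inclusive heritability.
A simulator of partial cross-fostering factorials (cultures x environments
x families, with reciprocal brood swaps and within-culture manipulation
controls) generates the designs that decouple `A` from `C`, and Monte-Carlo
diagnostics quantify when the two components are — and are not — separable.

## Worked example

```python
import numpy as np
from culturekin import (
    AnimalModel, DesignSpec, VarianceComponents, additive_matrix,
    apply_cross_fostering, cultural_relatedness_matrix, make_design,
    pedigree_overlap, simulate_phenotypes,
)

# 2 cultures x 2 environments, 38 families each, broods of 4,
# half of every brood cross-fostered into the other culture
spec = DesignSpec(n_cultures=2, n_environments=2, n_families_per_cell=38,
                  brood_size=4, swap_fraction=0.5, seed=7)
pop = apply_cross_fostering(make_design(spec), spec)
truth = VarianceComponents(sigma2_A=0.4, sigma2_C=0.3, sigma2_R=0.3)
pheno = simulate_phenotypes(pop, truth, seed=7)

ids = list(pheno["id"])
A = additive_matrix(pop.ped).subset(ids)
C = cultural_relatedness_matrix(pop.cped).subset(ids)
print(pedigree_overlap(A, C, cped=pop.cped).r_offdiag)

model = AnimalModel(random_effects={"A": A, "C": C},
                    fixed_effects=("environment",))
model.fit(pheno, pheno["y"].to_numpy())
print({k: round(v, 3) for k, v in model.variance_components_.items()})
print({k: round(v, 3) for k, v in model.heritability().items()
       if not k.startswith("se_")})
```

Output:

```
0.33002207505518355
{'A': 0.264, 'C': 0.4, 'residual': 0.277}
{'A': 0.281, 'C': 0.425, 'residual': 0.294}
```

The off-diagonal correlation between `A` and `C` has dropped from 1 (no
manipulation) to 0.33, and the REML fit on 608 offspring recovers the
generating partition (0.4, 0.3, 0.3) within sampling error — single-
replicate estimates at this size carry standard errors near 0.1, and
averaging over replicates (what `power_analysis` does) centers on the
truth. The last line gives the estimated narrow-sense heritability (0.28)
and cultural heritability (0.43) as shares of total phenotypic variance.
Dropping the cultural term and comparing by AIC, or testing it with the
boundary-corrected likelihood-ratio test (`lrt_component`), quantifies its
support; with `swap_fraction=0` instead, the same code reproduces the
confounded case where only `sigma2_A + sigma2_C` is identified.

There is also a CLI for file-based workflows:

```bash
culturekin simulate --config run.yaml --out simdir
culturekin amatrix --pedigree simdir/pedigree.tsv --out simdir
culturekin fit --pedigree simdir/pedigree.tsv \
    --cultural-pedigree simdir/cultural_pedigree.tsv \
    --phenotypes simdir/phenotypes.tsv --model run.yaml --out fit.txt
culturekin power --config run.yaml --swap-fractions 0,0.25,0.5 -R 20
```

See `docs/methods.md` for the model, numerical choices and limitations.

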