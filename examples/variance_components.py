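"""Estimate variance components for a repeated-record trait by REML.

Simulates ~2500 ejaculate records on 250 boars at heritability 0.30 and
repeatability 0.50, fits the repeatability animal model against the
pedigree relationship matrix, and prints the estimated components with
their asymptotic standard errors.  The estimates should bracket the
simulated truth.
"""

from wssgwas import build_A_inverse, build_model, estimate_reml
from wssgwas.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    seed=4,
    n_founders=80,
    n_generations=2,
    n_animals_target=300,
    n_snps=200,
    n_chromosomes=2,
    chrom_length_bp=8_000_000,
    h2=0.30,
    rep=0.50,
    records_per_animal=(10, 10),
    prop_phenotyped=250 / 300,
)
data = simulate_dataset(cfg)
print(f"{len(data.phenotypes)} records on "
      f"{data.phenotypes['animal'].nunique()} boars")

model = build_model(data.phenotypes, build_A_inverse(data.pedigree))
vc = estimate_reml(model)
print(vc.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"converged in {vc.n_iter} iterations "
      f"(simulated truth: h2 = 0.30, repeatability = 0.50)")
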