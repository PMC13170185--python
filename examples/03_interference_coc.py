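"""Crossover interference via the coefficient of coincidence (CoC).

Two simulations on one 25-Mb chromosome: Poisson placement (no
interference) and a gamma renewal process with shape nu = 8 (strong
interference). The chromosome is tiled into 2-Mb intervals; for each
interval pair CoC = observed double-CO frequency / product of single
frequencies. Independence gives CoC = 1 everywhere; interference pushes
CoC below 1 for nearby intervals.
"""

from xomap import (
    CoCConfig,
    GenomeMap,
    SimulationConfig,
    assign_intervals,
    coc_curve,
    coc_pairwise,
    simulate_population,
)

genome = GenomeMap({"chr1": 25_000_000})

for label, model, nu in [("no interference (Poisson)", "poisson", 1.0),
                         ("strong interference (gamma, nu=8)", "gamma", 8.0)]:
    config = SimulationConfig(
        genome=genome, co_model=model, nu=nu, lambda_c=2.0,
        markers_per_mb=2, n_individuals=5000,
        genotyping_error=0, missing_rate=0, seed=42,
    )
    _, truth, _ = simulate_population(config)
    result = coc_pairwise(assign_intervals(truth, genome, CoCConfig()))
    curve = coc_curve(result)
    print(f"\n{label}: pooled CoC by inter-interval distance")
    for _, row in curve.head(5).iterrows():
        print(f"  {row['distance']/1e6:4.0f} Mb  CoC = {row['pooled_coc']:.3f}"
              f"  ({row['n_pairs']:.0f} pairs)")
print(
    "\n# Under interference the 2-Mb bin sits far below 1 and CoC rises with"
    "\n# distance; under Poisson placement every bin fluctuates around 1."
)
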