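"""Fit the two-effect model and read off the variance-proportion row.

Fits M3 (species + species-by-domain effects, constant error variance) by
Gibbs sampling to a synthetic battery and prints the posterior mean +/- SD
share of latent variance per component — the row format of the published
model-comparison table.  Uses the desk preset (2,000 burn-in + 20,000
iterations; roughly half a minute).
"""

from modmind import (
    GenConfig, McmcConfig, ModelSpec, diagnostics, fit, generate,
    paper_design, variance_proportions,
)

config = GenConfig.from_proportions(
    paper_design(),
    {"species": 0.17, "species_domain": 0.17, "error": 0.66},
    seed=7, calibrate_realized=True,
)
dataset, _ = generate(config)

samples = fit(dataset, ModelSpec.from_name("M3"), McmcConfig.desk(seed=11))

row = variance_proportions(samples)
print(f"model {row.model}: posterior variance shares")
for term in ("error", "species", "species_domain"):
    print(f"  {term:15s} {row.mean[term]:.2f} ± {row.sd[term]:.2f}")
# Each share is sigma2_term / sum(active sigma2) per draw; values near the
# generating truth (0.66, 0.17, 0.17) mean the sampler attributes the
# latent variance to the right sources.

report = diagnostics(samples)
print("convergence warnings:", report["warnings"] or "none")
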