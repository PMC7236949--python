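"""From a pilot paired count matrix to a power estimate.

Generates a synthetic tumor/matched-normal style count matrix (500 genes,
50 pairs), fits the BNB model gene by gene, summarises the fitted baseline
means and dispersions at the 20th/50th/80th percentiles, and then estimates
power for a conservative design point: the 20th-percentile mean combined
with the 80th-percentile dispersion.
"""

from bnbpower import Scenario, estimate_power, generate_fixture, pilot_fit

counts, truth = generate_fixture(n_genes=500, n_pairs=50, seed=11)
pair_map = [(f"s{i:03d}", f"s{i:03d}_A", f"s{i:03d}_B") for i in range(1, 51)]

summary = pilot_fit(counts, pair_map, baseline="second")
print(f"fitted {summary.n_genes} genes "
      f"({summary.n_excluded_zero} all-zero excluded, "
      f"{summary.n_not_converged} non-converged)")
print("baseline mean percentiles:", {k: round(v, 1) for k, v in
                                     summary.mu_percentiles.items()})
print("dispersion percentiles:   ", {k: round(v, 3) for k, v in
                                     summary.phi_percentiles.items()})

mu = summary.mu_percentiles[20]
phi = summary.phi_percentiles[80]
res = estimate_power(
    Scenario(n=4, mu=mu, gamma=2.0, phi=phi, alpha=0.001, T=2000,
             test="bnb-lrt", critical_source="empirical", seed=2)
)
print(
    f"\ndesign point mu={mu:.1f} (20th pct), phi={phi:.2f} (80th pct): "
    f"power to detect a 2-fold change with n=4 pairs = "
    f"{res.power:.3f} +- {res.mc_se:.3f}"
)
print(
    "Low-expression, high-dispersion genes bound the design from below: a\n"
    "study powered for this point is at least as well powered for the rest\n"
    "of the transcriptome."
)
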