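"""Compare simulated null critical values with the chi-square(1) quantile.

Simulates the null distribution (no differential expression, gamma = 1) of
each test statistic on paired counts with n=10 pairs, baseline mean 10 and
dispersion 1, and prints the empirical critical value at alpha = 0.001 next
to the asymptotic chi-square(1) value 10.83.  The LRT statistics track
chi-square; the BNB Wald statistic has a heavier upper tail (using 10.83
would inflate its false positive rate) and the NB-LMM LRT a lighter one
(using 10.83 wastes power).
"""

from bnbpower import NullScenario, chi2_critical_value, critical_value, \
    simulate_null_stats

ALPHA = 0.001
T = 2000  # production runs use 20,000

print(f"empirical critical values at alpha={ALPHA}, T={T} "
      f"(chi-square(1): {chi2_critical_value(ALPHA):.2f})\n")
for test in ("bnb-lrt", "bnb-wald", "poisson-lmm-lrt", "nb-lmm-lrt"):
    nd = simulate_null_stats(
        NullScenario(n=10, mu=10.0, phi=1.0, test=test), T, seed=7
    )
    cv = critical_value(nd, ALPHA)
    note = f", {nd.n_negative} negative statistics retained" if nd.n_negative else ""
    print(f"  {test:18s} {cv:7.2f}   ({nd.stats.size} statistics, "
          f"{nd.n_failed} failed fits{note})")

print(
    "\nWith only 2,000 null statistics the 99.9th percentile is noisy; the\n"
    "ordering (Wald above chi-square, NB-LMM LRT below, both LRTs close) is\n"
    "the robust feature."
)
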