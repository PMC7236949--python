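"""Six-step simulation procedure for power estimation, grids and sample size.

For one scenario (n pairs, baseline mean mu, fold ratio gamma, dispersion
phi, level alpha, T simulations, a test, a critical-value source):

1. fix the inputs;
2. simulate T null datasets from BNB(mu, 1, phi) and T alternative datasets
   from BNB(mu, gamma, phi), n pairs each;
3. compute the chosen statistic on every null dataset;
4. take the 100(1-alpha)th percentile of the null statistics as the critical
   value (or the asymptotic chi-square(1) quantile);
5. compute the statistic on every alternative dataset;
6. report the fraction of alternative statistics strictly exceeding the
   critical value, with its binomial Monte Carlo standard error.

Null simulations always use gamma0 = 1 (no differential expression), also
when the alternative is a down-regulation (gamma < 1); the hypotheses are
two-sided around 1.  Within a grid the null bag is shared across gamma
values of the same (n, mu, phi, test) cell, and every cell derives its own
seeds from the master seed, so cells are pure functions of (scenario, seed)
and any execution order or parallel scheduler gives identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .empirical_null import (
    NullScenario,
    chi2_critical_value,
    critical_value,
    simulate_null_stats,
    simulate_stats,
    TESTS,
)

__all__ = [
    "Scenario",
    "PowerResult",
    "SampleSizeResult",
    "estimate_power",
    "power_grid",
    "sample_size_for_power",
]


@dataclass(frozen=True)
class Scenario:
    """One cell of the power study."""

    n: int
    mu: float
    gamma: float
    phi: float
    alpha: float
    T: int
    test: str = "bnb-lrt"
    critical_source: str = "empirical"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.T < 1:
            raise ValueError("n and T must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("mu", "gamma", "phi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive real")
        if self.test not in TESTS:
            raise ValueError(f"test must be one of {TESTS}")
        if self.critical_source not in ("empirical", "chi2"):
            raise ValueError("critical_source must be 'empirical' or 'chi2'")


@dataclass
class PowerResult:
    """Estimated power (or FPR) for one scenario cell plus Monte Carlo metadata."""

    scenario: Scenario
    power: float
    mc_se: float
    critical_value: float
    n_failed_null: int
    n_failed_alt: int

    def to_dict(self) -> dict:
        d = {
            "n": self.scenario.n,
            "mu": self.scenario.mu,
            "gamma": self.scenario.gamma,
            "phi": self.scenario.phi,
            "alpha": self.scenario.alpha,
            "T": self.scenario.T,
            "test": self.scenario.test,
            "critical_source": self.scenario.critical_source,
            "seed": self.scenario.seed,
            "power": self.power,
            "mc_se": self.mc_se,
            "critical_value": self.critical_value,
            "n_failed_null": self.n_failed_null,
            "n_failed_alt": self.n_failed_alt,
        }
        return d


def _null_seed(master: int, n, mu, phi, test) -> int:
    return derive_seed(master, "null", n, float(mu), float(phi), test)


def _alt_seed(master: int, n, mu, gamma, phi, test) -> int:
    return derive_seed(master, "alt", n, float(mu), float(gamma), float(phi), test)


def estimate_power(scenario: Scenario) -> PowerResult:
    """Estimate power for one scenario by the six-step procedure."""
    base = NullScenario(
        n=scenario.n, mu=scenario.mu, phi=scenario.phi, gamma0=1.0,
        test=scenario.test,
    )
    nd_null = simulate_null_stats(
        base, scenario.T,
        _null_seed(scenario.seed, scenario.n, scenario.mu, scenario.phi,
                   scenario.test),
    )
    if scenario.critical_source == "empirical":
        cv = critical_value(nd_null, scenario.alpha)
    else:
        cv = chi2_critical_value(scenario.alpha, df=1)
    nd_alt = simulate_stats(
        base, scenario.gamma, scenario.T,
        _alt_seed(scenario.seed, scenario.n, scenario.mu, scenario.gamma,
                  scenario.phi, scenario.test),
    )
    retained = nd_alt.stats.size
    power = float(np.mean(nd_alt.stats > cv)) if retained else float("nan")
    mc_se = float(np.sqrt(power * (1.0 - power) / retained)) if retained else float("nan")
    return PowerResult(
        scenario=scenario,
        power=power,
        mc_se=mc_se,
        critical_value=float(cv),
        n_failed_null=nd_null.n_failed,
        n_failed_alt=nd_alt.n_failed,
    )


def _evaluate_cell(n, mu, phi, test, gammas, alphas, critical_source, T,
                   master_seed) -> list[dict]:
    """All (gamma, alpha) results of one (n, mu, phi, test) cell.

    The null bag is simulated once and shared across gammas and alphas.
    """
    base = NullScenario(n=n, mu=mu, phi=phi, gamma0=1.0, test=test)
    nd_null = simulate_null_stats(base, T, _null_seed(master_seed, n, mu, phi, test))
    rows = []
    for gamma in gammas:
        nd_alt = simulate_stats(
            base, gamma, T, _alt_seed(master_seed, n, mu, gamma, phi, test)
        )
        retained = nd_alt.stats.size
        for alpha in alphas:
            if critical_source == "empirical":
                cv = critical_value(nd_null, alpha)
            else:
                cv = chi2_critical_value(alpha, df=1)
            power = float(np.mean(nd_alt.stats > cv)) if retained else float("nan")
            sc = Scenario(
                n=n, mu=mu, gamma=gamma, phi=phi, alpha=alpha, T=T, test=test,
                critical_source=critical_source, seed=master_seed,
            )
            rows.append(
                PowerResult(
                    scenario=sc,
                    power=power,
                    mc_se=float(np.sqrt(power * (1 - power) / retained))
                    if retained else float("nan"),
                    critical_value=float(cv),
                    n_failed_null=nd_null.n_failed,
                    n_failed_alt=nd_alt.n_failed,
                ).to_dict()
            )
    return rows


def power_grid(
    ns: Sequence[int],
    mus: Sequence[float],
    gammas: Sequence[float],
    phis: Sequence[float],
    alphas: Sequence[float],
    tests: Sequence[str] = ("bnb-lrt",),
    critical_source: str = "empirical",
    T: int = 20000,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Evaluate the cartesian scenario grid; long-format table, one row per cell.

    Cells are pure functions of (scenario, derived seed): two runs with the
    same master seed give identical tables regardless of ``n_jobs``.
    """
    cells = [
        (n, mu, phi, test)
        for test in tests for phi in phis for mu in mus for n in ns
    ]
    if not cells or not gammas or not alphas:
        raise ValueError("grid must be non-empty")
    if n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_cell)(
                n, mu, phi, test, list(gammas), list(alphas),
                critical_source, T, master_seed,
            )
            for (n, mu, phi, test) in cells
        )
    else:
        chunks = [
            _evaluate_cell(
                n, mu, phi, test, list(gammas), list(alphas),
                critical_source, T, master_seed,
            )
            for (n, mu, phi, test) in cells
        ]
    rows = [row for chunk in chunks for row in chunk]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["test", "phi", "mu", "n", "gamma", "alpha"]
    ).reset_index(drop=True)


@dataclass
class SampleSizeResult:
    """Smallest per-condition sample size reaching the target power (if any)."""

    n: Optional[int]
    target_power: float
    curve: pd.DataFrame  # columns n, power, mc_se, critical_value

    @property
    def found(self) -> bool:
        return self.n is not None


def sample_size_for_power(
    mu: float,
    phi: float,
    gamma: float,
    alpha: float,
    target_power: float,
    test: str = "bnb-lrt",
    critical_source: str = "empirical",
    n_range: Iterable[int] = range(3, 21),
    T: int = 20000,
    seed: int = 0,
) -> SampleSizeResult:
    """Smallest n in ``n_range`` whose estimated power reaches ``target_power``.

    Evaluates :func:`estimate_power` over ascending n and stops at the first
    success; when none qualifies the full power curve is returned with
    ``n=None``.
    """
    ns = sorted(set(int(n) for n in n_range))
    if not ns:
        raise ValueError("n_range must be non-empty")
    rows = []
    found = None
    for n in ns:
        res = estimate_power(
            Scenario(
                n=n, mu=mu, gamma=gamma, phi=phi, alpha=alpha, T=T,
                test=test, critical_source=critical_source, seed=seed,
            )
        )
        rows.append(
            {
                "n": n,
                "power": res.power,
                "mc_se": res.mc_se,
                "critical_value": res.critical_value,
            }
        )
        if res.power >= target_power:
            found = n
            break
    return SampleSizeResult(
        n=found, target_power=float(target_power), curve=pd.DataFrame(rows)
    )
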