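"""Pilot-data fitting and a synthetic paired count-matrix generator.

A pilot paired study (e.g. tumor / matched-normal pairs) supplies realistic
per-gene baseline means and dispersions for planning a new experiment: the
BNB model is fitted gene by gene and the 20th/50th/80th percentiles of the
fitted mu and phi summarise the expression landscape.  Picking, say, the
20th-percentile mean with the 80th-percentile dispersion gives a
conservative scenario for the power procedure.

The fixture generator emulates such a matrix (genes x 2*pairs integer
counts) from per-gene (mu, phi, gamma) laws so the workflow is runnable
without any external download; it is synthetic data, not a real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bnb import BNBParams, PairedCounts, bnb_fit, bnb_rvs
from .exceptions import NonIdentifiableError

__all__ = ["PilotSummary", "pilot_fit", "generate_fixture"]

PERCENTILE_LEVELS = (20, 50, 80)


@dataclass
class PilotSummary:
    """Per-gene BNB estimates and percentile summaries over converged genes."""

    per_gene: pd.DataFrame  # gene_id, mu_hat, gamma_hat, phi_hat, converged
    mu_percentiles: dict
    phi_percentiles: dict
    n_genes: int
    n_excluded_zero: int
    n_not_converged: int
    n_rounded_cells: int = 0


def _normalize_pair_map(pair_map) -> list[tuple[object, str, str]]:
    if isinstance(pair_map, pd.DataFrame):
        cols = list(pair_map.columns[:3])
        return [tuple(row) for row in pair_map[cols].itertuples(index=False)]
    if isinstance(pair_map, Mapping):
        return [(s, a, b) for s, (a, b) in pair_map.items()]
    return [tuple(entry) for entry in pair_map]


def pilot_fit(
    matrix: pd.DataFrame,
    pair_map,
    offsets: Optional[Mapping[str, float]] = None,
    baseline: str = "second",
) -> PilotSummary:
    """Fit the BNB model per gene on a paired count matrix.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples; either indexed by gene id or carrying a ``gene_id``
        first column.  Cells are non-negative counts.
    pair_map : mapping, DataFrame or sequence
        subject -> (colA, colB) column pairs; at least 2 subjects.
    offsets : mapping, optional
        Per-sample log normalization offsets.  Counts are divided by
        ``exp(offset)`` and rounded to integers (the BNB pmf lives on
        integers); the number of cells changed by rounding is recorded.
    baseline : {'second', 'first'}
        Which member of each pair is the baseline condition whose mean is
        reported as mu_hat (default the second, e.g. matched normal).

    Genes with all-zero counts are excluded (and counted); non-convergent
    fits are kept in the per-gene table but excluded from the percentile
    summaries.
    """
    if baseline not in ("second", "first"):
        raise ValueError("baseline must be 'second' or 'first'")
    matrix = matrix.copy()
    if "gene_id" in matrix.columns:
        matrix = matrix.set_index("gene_id")
    pairs = _normalize_pair_map(pair_map)
    if len(pairs) < 2:
        raise ValueError("pair_map must cover at least 2 subjects")
    used_cols: list[str] = []
    for _, a, b in pairs:
        for c in (a, b):
            if c not in matrix.columns:
                raise ValueError(f"pair_map column {c!r} not in the matrix")
            used_cols.append(c)
    sub = matrix[used_cols]
    vals = sub.to_numpy(dtype=float)
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("counts must be finite and non-negative")
    n_rounded = 0
    if offsets is not None:
        off = np.array([float(offsets.get(c, 0.0)) for c in used_cols])
        vals = vals / np.exp(off)[None, :]
    rounded = np.rint(vals)
    n_rounded = int(np.sum(rounded != vals))
    counts = pd.DataFrame(rounded.astype(np.int64), index=sub.index,
                          columns=used_cols)

    cols_a = [a for _, a, _ in pairs]
    cols_b = [b for _, _, b in pairs]
    if baseline == "second":
        base_cols, other_cols = cols_b, cols_a
    else:
        base_cols, other_cols = cols_a, cols_b

    records = []
    n_zero = 0
    # duplicate pair columns are possible in principle; use positional access
    base_idx = [used_cols.index(c) for c in base_cols]
    other_idx = [used_cols.index(c) for c in other_cols]
    arr = counts.to_numpy()
    for gi, gene in enumerate(counts.index):
        x = arr[gi, base_idx]
        y = arr[gi, other_idx]
        if x.sum() + y.sum() == 0:
            n_zero += 1
            continue
        try:
            fr = bnb_fit(PairedCounts(x=x, y=y))
        except NonIdentifiableError:
            n_zero += 1
            continue
        records.append(
            {
                "gene_id": gene,
                "mu_hat": fr.params.mu,
                "gamma_hat": fr.params.gamma,
                "phi_hat": fr.params.phi,
                "converged": fr.converged and not fr.boundary_flag,
            }
        )
    per_gene = pd.DataFrame(
        records,
        columns=["gene_id", "mu_hat", "gamma_hat", "phi_hat", "converged"],
    )
    conv = per_gene[per_gene["converged"]]
    mu_pct = {
        lv: float(np.percentile(conv["mu_hat"], lv)) if len(conv) else float("nan")
        for lv in PERCENTILE_LEVELS
    }
    phi_pct = {
        lv: float(np.percentile(conv["phi_hat"], lv)) if len(conv) else float("nan")
        for lv in PERCENTILE_LEVELS
    }
    return PilotSummary(
        per_gene=per_gene,
        mu_percentiles=mu_pct,
        phi_percentiles=phi_pct,
        n_genes=int(counts.shape[0]),
        n_excluded_zero=n_zero,
        n_not_converged=int((~per_gene["converged"]).sum()),
        n_rounded_cells=n_rounded,
    )


def _default_laws():
    # lognormal with median 50 for mu, median 0.2 for phi, median 1 for gamma
    return (
        lambda rng, k: rng.lognormal(np.log(50.0), 1.0, k),
        lambda rng, k: rng.lognormal(np.log(0.2), 1.0, k),
        lambda rng, k: rng.lognormal(0.0, 0.5, k),
    )


def generate_fixture(
    n_genes: int,
    n_pairs: int,
    mu_law=None,
    phi_law=None,
    gamma_law=None,
    seed: int = 0,
    out_counts=None,
    out_truth=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic paired count matrix plus the generating truth table.

    Laws are callables ``(rng, size) -> array`` (or scipy frozen
    distributions); defaults draw mu lognormal(median 50), phi
    lognormal(median 0.2), gamma lognormal(median 1).  Columns are
    ``s{i}_A`` (condition A, the y/fold-ratio side) and ``s{i}_B``
    (baseline).  With paths given, writes TSVs; the same seed always yields
    identical tables.
    """
    if n_genes < 0 or n_pairs < 1:
        raise ValueError("need n_genes >= 0 and n_pairs >= 1")
    d_mu, d_phi, d_gamma = _default_laws()
    laws = []
    for law, default in ((mu_law, d_mu), (phi_law, d_phi), (gamma_law, d_gamma)):
        if law is None:
            law = default
        elif hasattr(law, "rvs"):
            frozen = law
            law = lambda rng, k, _f=frozen: _f.rvs(size=k, random_state=rng)
        laws.append(law)
    rng = np.random.default_rng(seed)
    mu = laws[0](rng, n_genes)
    phi = laws[1](rng, n_genes)
    gamma = laws[2](rng, n_genes)
    cols = [f"s{i:03d}_{c}" for i in range(1, n_pairs + 1) for c in ("A", "B")]
    rows = np.empty((n_genes, 2 * n_pairs), dtype=np.int64)
    for g in range(n_genes):
        pc = bnb_rvs(BNBParams(mu[g], gamma[g], phi[g]), n_pairs, rng)
        rows[g, 0::2] = pc.y  # condition A carries the fold ratio
        rows[g, 1::2] = pc.x  # condition B is baseline
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    counts = pd.DataFrame(rows, columns=cols)
    counts.insert(0, "gene_id", gene_ids)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "mu": mu, "gamma": gamma, "phi": phi}
    )
    if out_counts is not None:
        counts.to_csv(out_counts, sep="\t", index=False)
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return counts, truth
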