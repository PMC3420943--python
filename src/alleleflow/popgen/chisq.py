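"""Pearson chi-square test on species x category contingency tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    df: int
    p: float
    warnings: tuple[str, ...] = ()
    mc_p: float | None = None


def category_chisq(
    table,
    monte_carlo: bool = False,
    n_mc: int = 10_000,
    seed: int = 0,
) -> ChisqResult:
    """Pearson chi-square (no continuity correction) on an r x c table.

    Zero marginal rows/columns are dropped with a warning.  Expected
    counts below 5 trigger a small-sample warning; with
    ``monte_carlo=True`` a seeded Monte-Carlo p-value over ``n_mc``
    random tables with the observed margins is reported alongside.
    """
    if isinstance(table, pd.DataFrame):
        counts = table.to_numpy(dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(counts < 0):
        raise ValueError("negative counts")

    notes: list[str] = []
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        msg = "dropped zero-marginal rows/columns from contingency table"
        warnings.warn(msg)
        notes.append(msg)
        counts = counts[row_keep][:, col_keep]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")

    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    mc_p = None
    if (expected < 5).any():
        msg = "expected counts < 5; chi-square approximation may be poor"
        warnings.warn(msg)
        notes.append(msg)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(
            counts.sum(axis=1).astype(int), counts.sum(axis=0).astype(int)
        )
        sims = dist.rvs(n_mc, random_state=rng)
        stat = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        mc_p = float((1 + np.count_nonzero(stat >= chi2 - 1e-12)) / (n_mc + 1))
    return ChisqResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        warnings=tuple(notes),
        mc_p=mc_p,
    )
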