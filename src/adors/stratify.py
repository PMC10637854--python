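"""Decile risk stratification.

Samples are sorted by risk score and divided into (near-)equal bins;
the case count per bin shows how well score rank tracks observed risk.
A well-calibrated score exhibits a "staircase": case counts rise
monotonically from the lowest to the highest decile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DecileTable", "decile_table", "staircase_statistic"]


@dataclass
class DecileTable:
    """Per-bin sample/case counts, ordered low to high score."""

    table: pd.DataFrame  # columns: bin, n, cases, prevalence
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def decile_table(scores, labels, sample_ids=None, n_bins: int = 10) -> DecileTable:
    """Bin samples by ascending score and count cases per bin.

    Stable sort with ties broken by sample ID; the first ``n mod
    n_bins`` bins (low-score end) take the extra sample each.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} samples, got {n}")
    if sample_ids is None:
        sample_ids = np.arange(n)
    order = sorted(range(n), key=lambda i: (scores[i], str(sample_ids[i])))
    big = -(-n // n_bins)  # ceil
    small = n // n_bins
    n_big = n % n_bins
    sizes = [big] * n_big + [small] * (n_bins - n_big)
    rows, start = [], 0
    for b, size in enumerate(sizes, 1):
        idx = order[start : start + size]
        start += size
        cases = int(labels[idx].sum())
        rows.append(
            {"bin": b, "n": size, "cases": cases, "prevalence": cases / size if size else np.nan}
        )
    return DecileTable(table=pd.DataFrame(rows), n_bins=n_bins)


def staircase_statistic(table: DecileTable) -> float:
    """Spearman correlation between bin index and case count.

    1.0 for strictly increasing counts (a perfect staircase); all-equal
    counts return 0.0 by convention (with a warning).
    """
    cases = table.table["cases"].to_numpy()
    if np.ptp(cases) == 0:
        import warnings

        warnings.warn("all bins have equal case counts; staircase statistic 0 by convention")
        return 0.0
    rho = stats.spearmanr(table.table["bin"], cases).statistic
    return float(rho)
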