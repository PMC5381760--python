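"""Biome x phenotype contingency table and its association statistics.

Implements the full statistics block of a stratified two-column phenotype
table: expected counts under independence, three percentage blocks, adjusted
standardized residuals, Pearson chi-square, likelihood-ratio G and the
linear-by-linear (Mantel-Haenszel trend) statistic with configurable ordinal
scores.  Everything is computed from the raw counts; no continuity correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import LocationRecord

__all__ = ["ContingencyResult", "contingency_table", "contingency_from_counts",
           "phenotype_frequency"]

PHENOTYPE_COLUMNS = ("non_melanistic", "melanistic")


@dataclass
class ContingencyResult:
    biomes: list[str]
    counts: np.ndarray            # (R, 2) ints, columns = PHENOTYPE_COLUMNS
    expected: np.ndarray
    pct_within_landscape: np.ndarray
    pct_within_group: np.ndarray
    pct_of_total: np.ndarray
    adjusted_residuals: np.ndarray
    chi_square: float
    likelihood_ratio: float
    linear_by_linear: float
    dof: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Long-form table mirroring the published layout."""
        blocks = {
            "count": self.counts,
            "expected": self.expected,
            "pct_within_landscape": self.pct_within_landscape,
            "pct_within_group": self.pct_within_group,
            "pct_of_total": self.pct_of_total,
            "adjusted_residual": self.adjusted_residuals,
        }
        rows = []
        for i, biome in enumerate(self.biomes):
            for stat, arr in blocks.items():
                rows.append(
                    {
                        "biome": biome,
                        "statistic": stat,
                        "non_melanistic": arr[i, 0],
                        "melanistic": arr[i, 1],
                        "total": arr[i].sum() if stat in ("count", "expected") else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def stats_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "chi_square": self.chi_square,
                "likelihood_ratio": self.likelihood_ratio,
                "linear_by_linear": self.linear_by_linear,
                "dof": self.dof,
                "n": self.n,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def contingency_from_counts(
    counts: np.ndarray,
    biomes: Sequence[str] | None = None,
    row_scores: Sequence[float] | None = None,
    col_scores: Sequence[float] = (0.0, 1.0),
) -> ContingencyResult:
    """All Table-style statistics from a raw (R, 2) count matrix.

    ``row_scores`` / ``col_scores`` are the ordinal scores of the
    linear-by-linear statistic; defaults are table row order 1..R and
    phenotype 0/1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must be an (R, 2) matrix")
    if counts.sum() <= 0:
        raise ValueError("empty contingency table")
    if biomes is None:
        biomes = [f"row_{i}" for i in range(counts.shape[0])]
    biomes = list(biomes)

    nonzero = counts.sum(axis=1) > 0
    if not nonzero.all():
        import warnings

        dropped = [b for b, ok in zip(biomes, nonzero) if not ok]
        warnings.warn(f"dropping biomes with zero total: {dropped}")
        counts = counts[nonzero]
        biomes = [b for b, ok in zip(biomes, nonzero) if ok]

    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n

    chi_square = float(((counts - expected) ** 2 / expected).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / expected)
    terms[counts == 0] = 0.0  # 0 * ln 0 := 0
    likelihood_ratio = float(2.0 * terms.sum())

    adj = (counts - expected) / np.sqrt(
        expected * (1.0 - row[:, None] / n) * (1.0 - col[None, :] / n)
    )

    if row_scores is None:
        row_scores = np.arange(1, counts.shape[0] + 1, dtype=float)
    rs = np.asarray(row_scores, dtype=float)
    cs = np.asarray(col_scores, dtype=float)
    w = counts / n
    mu_r = (rs[:, None] * w).sum()
    mu_c = (cs[None, :] * w).sum()
    cov = ((rs[:, None] - mu_r) * (cs[None, :] - mu_c) * w).sum()
    var_r = (((rs - mu_r) ** 2)[:, None] * w).sum()
    var_c = (((cs - mu_c) ** 2)[None, :] * w).sum()
    if var_r > 0 and var_c > 0:
        r_corr = cov / np.sqrt(var_r * var_c)
        linear_by_linear = float((n - 1.0) * r_corr**2)
    else:
        linear_by_linear = 0.0

    return ContingencyResult(
        biomes=biomes,
        counts=counts.astype(int),
        expected=expected,
        pct_within_landscape=100.0 * counts / row[:, None],
        pct_within_group=100.0 * counts / col[None, :],
        pct_of_total=100.0 * counts / n,
        adjusted_residuals=adj,
        chi_square=chi_square,
        likelihood_ratio=likelihood_ratio,
        linear_by_linear=linear_by_linear,
        dof=int((counts.shape[0] - 1) * (counts.shape[1] - 1)),
        n=int(round(n)),
    )


def contingency_table(
    records: Sequence[LocationRecord],
    biome_order: Sequence[str] | None = None,
    row_scores: Sequence[float] | None = None,
) -> ContingencyResult:
    """Build the biome x phenotype table from records with assigned biomes.

    Only confirmed phenotypes enter the table; records without a biome are
    excluded.
    """
    usable = [
        r
        for r in records
        if r.phenotype in PHENOTYPE_COLUMNS and r.biome is not None
    ]
    if not usable:
        raise ValueError("no records with confirmed phenotype and assigned biome")
    if biome_order is None:
        biome_order = sorted({r.biome for r in usable})
    index = {b: i for i, b in enumerate(biome_order)}
    counts = np.zeros((len(biome_order), 2))
    for r in usable:
        if r.biome in index:
            counts[index[r.biome], PHENOTYPE_COLUMNS.index(r.phenotype)] += 1
    return contingency_from_counts(counts, biomes=biome_order, row_scores=row_scores)


def phenotype_frequency(
    records: Sequence[LocationRecord],
    denominator_policy: str = "confirmed_only",
) -> dict[str, float | int]:
    """Melanism frequency (%) under an explicit denominator policy.

    ``confirmed_only`` divides by confirmed melanistic + non-melanistic
    records; ``all_records`` divides by every record including unconfirmed.
    """
    if not records:
        raise ValueError("phenotype_frequency requires at least one record")
    n_mel = sum(r.phenotype == "melanistic" for r in records)
    n_non = sum(r.phenotype == "non_melanistic" for r in records)
    n_unc = sum(r.phenotype == "unconfirmed_melanistic" for r in records)
    if denominator_policy == "confirmed_only":
        denom = n_mel + n_non
    elif denominator_policy == "all_records":
        denom = n_mel + n_non + n_unc
    else:
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    freq = 100.0 * n_mel / denom if denom else 0.0
    return {
        "frequency_pct": freq,
        "n_melanistic": n_mel,
        "n_non_melanistic": n_non,
        "n_unconfirmed": n_unc,
        "denominator": denom,
    }
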