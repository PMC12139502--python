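"""Proteome-transcriptome integration.

Three analyses on matched protein (FOT) and transcript (FPKM) matrices:

* **Spearman correlation profiles** — per-gene rank correlation across matched
  design groups and per-group rank correlation across genes, with medians of
  both. Zero-variance vectors yield an undefined correlation and are excluded
  from the medians.
* **Intercept over-representation** — pool (x = log2 FPKM, y = log2 FOT) pairs,
  fit an ordinary least-squares baseline y = m*x + b0, and rank genes by the
  vertical deviation d_i = y_i - m*x_i (the intercept of the line with baseline
  slope through the point). The top 5% of deviations are called
  protein-overexpressed, the bottom 5% RNA-overexpressed. Adding a constant to
  all y shifts b0 but not the ranking.
* **Ratio discordance** — per cell-type protein/RNA ratios; a gene is flagged
  in a cell-type when the average ratio over the four cell-types is at least
  ``factor`` (default 3) times the ratio in that cell-type, i.e. the cell-type
  translates disproportionately little protein per transcript relative to the
  gene's own average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import QuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "InterceptRanking",
    "correlate_protein_rna",
    "intercept_overrepresentation",
    "ratio_discordance",
]


class IntegrationError(ValueError):
    pass


@dataclass
class CorrelationProfile:
    per_gene: pd.Series  # Spearman rho across matched groups, NaN = undefined
    per_group: pd.Series  # Spearman rho across genes
    median_per_gene: float
    median_per_group: float


def _match(protein: QuantMatrix, rna: QuantMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = protein.values.index.intersection(rna.values.index)
    if len(genes) < len(protein.values.index) or len(genes) < len(rna.values.index):
        logger.info(
            "gene intersection: %d of %d protein / %d RNA features",
            len(genes), len(protein.values.index), len(rna.values.index),
        )
    if len(genes) == 0:
        raise IntegrationError("no shared gene IDs between the matrices")
    pm, rm = protein.group_means().loc[genes], rna.group_means().loc[genes]
    shared = [g for g in pm.columns if g in set(rm.columns)]
    if not shared:
        raise IntegrationError("no shared design groups between the matrices")
    return pm[shared], rm[shared]


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average-rank ties; NaN when undefined (<3 points or
    zero variance on either side)."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlate_protein_rna(
    protein: QuantMatrix, rna: QuantMatrix
) -> CorrelationProfile:
    """Spearman correlation profile between matched protein and RNA matrices.

    Matching uses the intersection of gene IDs and of design group labels;
    replicates are collapsed to group means first.
    """
    pm, rm = _match(protein, rna)
    per_gene = pd.Series(
        [_spearman(pm.loc[g].to_numpy(float), rm.loc[g].to_numpy(float)) for g in pm.index],
        index=pm.index,
        name="rho",
    )
    per_group = pd.Series(
        {g: _spearman(pm[g].to_numpy(float), rm[g].to_numpy(float)) for g in pm.columns},
        name="rho",
    )
    return CorrelationProfile(
        per_gene=per_gene,
        per_group=per_group,
        median_per_gene=float(per_gene.median(skipna=True)),
        median_per_group=float(per_group.median(skipna=True)),
    )


@dataclass
class InterceptRanking:
    slope: float
    intercept: float
    deviations: pd.Series  # d_i = y_i - slope * x_i, sorted descending
    protein_over: frozenset[str]
    rna_over: frozenset[str]
    tail: float
    degenerate: bool = field(default=False)  # all deviations equal (collinear input)


def intercept_overrepresentation(
    pairs: pd.DataFrame, tail: float = 0.05
) -> InterceptRanking:
    """Rank genes by deviation from the pooled log2 protein-vs-RNA baseline.

    ``pairs`` must hold one row per gene with columns ``x`` (log2 FPKM) and
    ``y`` (log2 FOT). The top ceil(tail*n) deviations are labelled
    protein-overexpressed, the bottom ceil(tail*n) RNA-overexpressed; ties
    break on the gene ID for determinism. Requires >= 40 pairs so the two
    tails cannot overlap at the default 5%.
    """
    if not {"x", "y"} <= set(pairs.columns):
        raise IntegrationError("pairs needs 'x' and 'y' columns")
    if not (0 < tail < 0.5):
        raise IntegrationError("tail fraction must be in (0, 0.5)")
    pairs = pairs.dropna(subset=["x", "y"])
    n = len(pairs)
    if n < 40:
        raise IntegrationError(f"need >= 40 finite pairs, got {n}")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise IntegrationError("zero variance in x: baseline slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    d = y - slope * x
    order = sorted(range(n), key=lambda i: (-d[i], str(pairs.index[i])))
    dev = pd.Series(d[order], index=pairs.index[order], name="deviation")
    k = math.ceil(tail * n)
    protein_over = frozenset(dev.index[:k])
    rna_over = frozenset(dev.index[-k:])
    return InterceptRanking(
        slope=float(slope),
        intercept=float(intercept),
        deviations=dev,
        protein_over=protein_over,
        rna_over=rna_over,
        tail=tail,
        degenerate=bool(np.ptp(d) <= 1e-9 * max(1.0, float(np.max(np.abs(d))))),
    )


def pairs_from_matrices(
    protein: QuantMatrix, rna: QuantMatrix, group: str, features=None
) -> pd.DataFrame:
    """Build the (x=log2 FPKM, y=log2 FOT) pair table for one design group.

    Zeros are guarded with each matrix's smallest positive value as a
    pseudo-count before the log. ``features`` optionally restricts the pairs
    (e.g. to proteins actually detected in that group — imputed-only rows
    carry no information about translation and distort the baseline fit).
    """
    pm, rm = _match(protein, rna)
    if group not in pm.columns:
        raise IntegrationError(f"group {group!r} not shared by both designs")
    if features is not None:
        keep = pm.index.intersection(pd.Index(sorted(features)))
        pm, rm = pm.loc[keep], rm.loc[keep]
    y = _safe_log2(pm[group])
    x = _safe_log2(rm[group])
    return pd.DataFrame({"x": x, "y": y})


def _safe_log2(s: pd.Series) -> pd.Series:
    arr = s.to_numpy(dtype=float)
    pos = arr[np.isfinite(arr) & (arr > 0)]
    if pos.size == 0:
        raise IntegrationError("no positive values to log-transform")
    return np.log2(s.where(s > 0, other=float(pos.min())))


def ratio_discordance(
    protein: QuantMatrix,
    rna: QuantMatrix,
    factor: float = 3.0,
    flip: bool = False,
) -> pd.DataFrame:
    """Flag genes whose protein/RNA ratio in one cell-type lags the average.

    Per gene and cell-type c, with r_c = protein_c / RNA_c (group means; RNA
    zeros get the matrix's smallest positive FPKM as pseudo-count), the gene is
    flagged in c when mean_ct(r) >= factor * r_c. ``flip`` reverses the
    inequality direction (r_c >= factor * mean) for the alternative reading of
    the rule.
    """
    pm, rm = _match(protein, rna)
    rarr = rm.to_numpy(dtype=float)
    pos = rarr[np.isfinite(rarr) & (rarr > 0)]
    if pos.size == 0:
        raise IntegrationError("RNA matrix has no positive values")
    rm = rm.where(rm > 0, other=float(pos.min()))
    ratios = pm / rm
    avg = ratios.mean(axis=1)
    rows = []
    for group in ratios.columns:
        r_c = ratios[group]
        if flip:
            flagged = r_c >= factor * avg
            stat = (r_c / avg).to_numpy(dtype=float)
        else:
            flagged = avg >= factor * r_c
            stat = (avg / r_c).to_numpy(dtype=float)
        rows.append(
            pd.DataFrame(
                {
                    "feature": ratios.index,
                    "group": group,
                    "rule": "ratio_discordance",
                    "statistic": stat,
                    "threshold": float(factor),
                    "passed": flagged.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
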