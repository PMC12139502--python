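"""Group-restricted expression signatures.

Three rules, all operating on FOT matrices after collapsing replicates by
arithmetic mean per group:

* **enhanced** — a protein is enhanced in a cell-type when its mean there is at
  least ``fold`` (default 2) times the geometric mean of its means in the other
  cell-types;
* **ubiquitous** — a protein is ubiquitous across regions when its median
  log10(FOT) over regions is strictly greater than ``threshold_log10``
  (default -2);
* **enriched ligand** — a ligand is enriched in a cell-type when its mean there
  is at least ``fold`` (default 1.5) times the arithmetic mean over *all*
  cell-types (the focal one included).

A fourth utility classifies DNA-binding proteins into TF / TC / DNA-binding /
other by list precedence.

All calls are returned as tidy DataFrames with one row per (feature, group)
decision, carrying the rule, the statistic that justified it, the threshold
used, and the boolean outcome. The enhanced rule is scale-invariant (FOT is a
per-sample fraction, so any global rescaling cancels in the ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import QuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "call_enhanced_proteins",
    "call_ubiquitous_proteins",
    "call_enriched_ligands",
    "classify_tf_annotations",
    "TFAnnotation",
]


class SignatureError(ValueError):
    pass


def _geomean_eps(matrix: QuantMatrix) -> float:
    """Zero guard for geometric means: 1e-3 x the smallest positive value.

    Post-imputation matrices have no zeros, so this path is rarely taken, but
    degenerate inputs must not crash the rule.
    """
    arr = matrix.values.to_numpy(dtype=float)
    pos = arr[np.isfinite(arr) & (arr > 0)]
    if pos.size == 0:
        raise SignatureError("matrix has no positive values")
    return float(pos.min()) * 1e-3


def call_enhanced_proteins(matrix: QuantMatrix, fold: float = 2.0) -> pd.DataFrame:
    """Cell-type-enhanced calls: mean in one group vs geometric mean of the rest.

    Returns one row per (feature, group) with the ratio for every feature, so
    callers can inspect near-misses; ``passed`` marks ratio >= fold. A feature
    may pass in more than one group only when the rule holds independently
    (possible with more than a handful of groups).
    """
    if matrix.scale != "FOT":
        raise SignatureError(f"enhanced rule expects FOT scale, got {matrix.scale!r}")
    means = matrix.group_means()
    if means.shape[1] < 2:
        raise SignatureError("enhanced rule needs at least 2 design groups")
    eps = _geomean_eps(matrix)
    logm = np.log(means.to_numpy(dtype=float) + eps)
    rows = []
    for j, group in enumerate(means.columns):
        others = np.delete(logm, j, axis=1)
        geo = np.exp(others.mean(axis=1))  # geometric mean of (means + eps)
        ratio = means.iloc[:, j].to_numpy(dtype=float) / geo
        rows.append(
            pd.DataFrame(
                {
                    "feature": means.index,
                    "group": group,
                    "rule": "enhanced",
                    "statistic": ratio,
                    "threshold": float(fold),
                    "passed": ratio >= fold,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def call_ubiquitous_proteins(
    matrix: QuantMatrix, threshold_log10: float = -2.0
) -> pd.DataFrame:
    """Ubiquitous-across-regions calls: median log10(FOT) strictly above threshold."""
    if matrix.scale != "FOT":
        raise SignatureError(f"ubiquitous rule expects FOT scale, got {matrix.scale!r}")
    means = matrix.group_means()
    arr = means.to_numpy(dtype=float)
    if np.nanmin(arr) <= 0:
        raise SignatureError(
            "nonpositive FOT cannot enter log10; impute the matrix first"
        )
    med = np.median(np.log10(arr), axis=1)
    return pd.DataFrame(
        {
            "feature": means.index,
            "group": "all_regions",
            "rule": "ubiquitous",
            "statistic": med,
            "threshold": float(threshold_log10),
            "passed": med > threshold_log10,
        }
    )


def call_enriched_ligands(
    matrix: QuantMatrix, ligand_universe, fold: float = 1.5
) -> pd.DataFrame:
    """Cell-type-enriched ligand calls: group mean vs average over all groups.

    The denominator includes the focal cell-type ("average level in the four
    cell-types" read literally); the comparison is inclusive (>=). Ligands
    absent from the matrix are skipped with a logged warning.
    """
    if matrix.scale != "FOT":
        raise SignatureError(f"ligand rule expects FOT scale, got {matrix.scale!r}")
    ligands = sorted(set(ligand_universe))
    present = [g for g in ligands if g in matrix.values.index]
    missing = sorted(set(ligands) - set(present))
    if missing:
        logger.warning("%d ligand(s) absent from the matrix: %s ...", len(missing), missing[:5])
    means = matrix.group_means().loc[present]
    overall = means.mean(axis=1)
    rows = []
    for group in means.columns:
        ratio = means[group] / overall
        rows.append(
            pd.DataFrame(
                {
                    "feature": means.index,
                    "group": group,
                    "rule": "enriched_ligand",
                    "statistic": ratio.to_numpy(dtype=float),
                    "threshold": float(fold),
                    "passed": means[group].to_numpy() >= fold * overall.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class TFAnnotation:
    gene_id: str
    cls: str  # TF | TC | DNA-binding | other
    source_list: str


def classify_tf_annotations(
    gene_ids,
    tf_list,
    tc_list,
    descriptions: dict[str, str] | None = None,
) -> list[TFAnnotation]:
    """Classify genes as TF > TC > DNA-binding > other (list precedence).

    A gene falls back to the DNA-binding class when its free-text description
    contains the literal substring "DNA-binding" (case-insensitive).
    """
    tf_set, tc_set = set(tf_list), set(tc_list)
    descriptions = descriptions or {}
    out = []
    for g in gene_ids:
        if g in tf_set:
            out.append(TFAnnotation(g, "TF", "tf_list"))
        elif g in tc_set:
            out.append(TFAnnotation(g, "TC", "tc_list"))
        elif "dna-binding" in descriptions.get(g, "").lower():
            out.append(TFAnnotation(g, "DNA-binding", "description"))
        else:
            out.append(TFAnnotation(g, "other", ""))
    return out
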