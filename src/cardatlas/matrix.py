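"""Feature-by-sample abundance matrices with a declared scale and a sample design.

The :class:`QuantMatrix` is the pipeline's shared in-memory container: a pandas
DataFrame of non-negative abundances (features in rows, samples in columns), a
``scale`` tag recording which quantification stage produced it (raw peptide-summed
``intensity``, ``iBAQ``, fraction-of-total ``FOT``, log-transformed variants, or
transcript ``FPKM``), and a ``design`` table mapping each sample to its group
(cell-type, region, or region+condition) and replicate.

Scale transitions only happen through declared operations (FOT normalisation,
log transforms), so downstream rules can assert the scale they expect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LINEAR_SCALES = {"intensity", "iBAQ", "FOT", "FPKM"}
LOG_SCALES = {"log10FOT", "log2FOT", "log2FPKM", "log2intensity", "log10FPKM"}
VALID_SCALES = LINEAR_SCALES | LOG_SCALES


class MatrixError(ValueError):
    """Raised when a QuantMatrix violates its invariants."""


@dataclass
class QuantMatrix:
    """Features x samples abundance matrix.

    Parameters
    ----------
    values : pd.DataFrame
        Abundances, index = feature IDs, columns = sample IDs. NaN marks a
        missing (unobserved) value on linear scales.
    scale : str
        One of ``intensity, iBAQ, FOT, FPKM`` or their log variants.
    design : pd.DataFrame
        Indexed by sample ID with at least a ``group`` column; ``replicate``
        and extra columns (``region``, ``condition``) are carried through.
    """

    values: pd.DataFrame
    scale: str
    design: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise MatrixError(f"unknown scale {self.scale!r}")
        if not self.values.columns.is_unique:
            raise MatrixError("sample IDs must be unique")
        if not self.values.index.is_unique:
            raise MatrixError("feature IDs must be unique")
        if self.design is None:
            self.design = pd.DataFrame(
                {"group": list(self.values.columns)}, index=self.values.columns
            )
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise MatrixError(f"samples absent from design: {missing[:5]}")
        if self.scale in LINEAR_SCALES:
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) < 0:
                raise MatrixError(f"negative values on linear scale {self.scale!r}")

    # -- basic views ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.design.loc[self.sample_ids, "group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        d = self.design.loc[self.sample_ids]
        return list(d.index[d["group"] == group])

    def group_means(self) -> pd.DataFrame:
        """Arithmetic mean over replicates, one column per design group.

        NaN cells are ignored sample-wise (mean over observed replicates).
        """
        cols = {g: self.values[self.samples_of(g)].mean(axis=1) for g in self.groups()}
        return pd.DataFrame(cols)

    # -- scale transitions ------------------------------------------------
    def log10(self) -> "QuantMatrix":
        self._require_positive("log10")
        return QuantMatrix(np.log10(self.values), f"log10{self.scale}", self.design)

    def log2(self) -> "QuantMatrix":
        self._require_positive("log2")
        return QuantMatrix(np.log2(self.values), f"log2{self.scale}", self.design)

    def _require_positive(self, op: str) -> None:
        if self.scale not in LINEAR_SCALES:
            raise MatrixError(f"{op} only applies to linear scales, not {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=np.inf) <= 0:
            raise MatrixError(f"nonpositive values cannot enter {op}")

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix TSV plus ``<path>.json`` sidecar and ``<path>.design.tsv``."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="feature", float_format="%.8g")
        sidecar = {"scale": self.scale, "n_features": len(self.values), "n_samples": self.values.shape[1]}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")
        self.design.to_csv(str(path) + ".design.tsv", sep="\t", index_label="sample")

    @classmethod
    def read_tsv(
        cls, path: str | Path, scale: str | None = None, design_path: str | Path | None = None
    ) -> "QuantMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="feature")
        if scale is None:
            sidecar = Path(str(path) + ".json")
            if not sidecar.exists():
                raise MatrixError(f"no scale given and no sidecar at {sidecar}")
            scale = json.loads(sidecar.read_text())["scale"]
        if design_path is None:
            cand = Path(str(path) + ".design.tsv")
            design_path = cand if cand.exists() else None
        design = (
            pd.read_csv(design_path, sep="\t", index_col="sample")
            if design_path is not None
            else None
        )
        return cls(values, scale, design)


def make_design(
    samples: list[str],
    groups: list[str],
    replicates: list[int] | None = None,
    **extra: list,
) -> pd.DataFrame:
    """Assemble a design table from parallel per-sample lists."""
    data: dict[str, list] = {"group": groups}
    if replicates is not None:
        data["replicate"] = replicates
    data.update(extra)
    return pd.DataFrame(data, index=pd.Index(samples, name="sample"))
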