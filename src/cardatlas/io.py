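"""Readers and writers for the pipeline's plain-text formats.

Formats handled here:

* identified-peptide tables — TSV with columns ``sequence``, ``proteins``
  (``;``-separated accessions), ``ion_score`` and one intensity column per
  sample (empty cell = missing);
* protein FASTA (via :mod:`pyteomics.fasta`);
* GMT gene-set collections (name, description, genes...);
* two/three-column edge lists (ligand-receptor pairs, pathway edges, TF->TG).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pyteomics import fasta as _fasta

from .quantify import PeptideRecord, PeptideTable

_META_COLS = ("sequence", "proteins", "ion_score")


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    rows = []
    for rec in table.records:
        row: dict[str, object] = {
            "sequence": rec.sequence,
            "proteins": ";".join(sorted(rec.proteins)),
            "ion_score": rec.ion_score,
        }
        row.update({s: rec.intensities.get(s, float("nan")) for s in table.sample_ids})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLS) + list(table.sample_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_peptide_table(path: str | Path) -> PeptideTable:
    df = pd.read_csv(path, sep="\t")
    sample_ids = [c for c in df.columns if c not in _META_COLS]
    records = []
    for _, r in df.iterrows():
        intens = {s: float(r[s]) for s in sample_ids if pd.notna(r[s])}
        records.append(
            PeptideRecord(
                sequence=str(r["sequence"]),
                proteins=frozenset(str(r["proteins"]).split(";")),
                ion_score=float(r["ion_score"]),
                intensities=intens,
            )
        )
    return PeptideTable(records=records, sample_ids=sample_ids)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    entries = [(acc, seq) for acc, seq in sequences.items()]
    _fasta.write(entries, str(path), file_mode="w")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with _fasta.read(str(path)) as reader:
        for entry in reader:
            acc = entry.description.split()[0]
            out[acc] = entry.sequence
    return out


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique non-empty sets plus a source tag."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.source}\t{genes}\n")


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    src = source
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, *genes = parts
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            src = src or desc
    return GeneSetCollection(sets, source=src or str(path))


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))
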