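"""Label-free protein quantification from identified-peptide tables.

The stage order is fixed: peptide filtering (length >= 7, ion score >= 20) ->
parsimony protein inference (greedy minimum set cover) -> unique-peptide filter
(>= 2 unique peptides per group) -> summed peptide intensity -> iBAQ (divide by
the count of theoretically observable tryptic peptides) -> FOT normalisation
(fraction of total iBAQ per sample, x1e5) -> global-minimum imputation.

iBAQ divides a protein's summed peptide intensity by the number of fully
tryptic peptides of 7-30 residues its sequence can yield (Keil rule: no
cleavage C-terminal to K/R when followed by proline; zero missed cleavages —
the conventional iBAQ count even when the search allowed more). FOT rescales
each sample so identified proteins sum to 1e5, making columns comparable
across experiments. Shared peptides are razor-assigned: each peptide's
intensity counts once, toward the group that claimed it during the greedy
cover. Missing values are imputed with the smallest observed value of the
whole matrix, after FOT normalisation (the exact column-sum invariant
therefore holds pre-imputation and is asserted there).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import QuantMatrix, make_design

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "PeptideRecord",
    "PeptideTable",
    "ProteinGroup",
    "filter_peptides",
    "infer_proteins_parsimony",
    "filter_protein_groups",
    "count_theoretical_peptides",
    "digest_tryptic",
    "compute_ibaq",
    "normalize_fot",
    "impute_missing",
    "quantify_peptides",
]


class QuantifyError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide: sequence, mapped accessions, score, intensities."""

    sequence: str
    proteins: frozenset[str]
    ion_score: float
    intensities: dict[str, float] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise QuantifyError(f"peptide {self.sequence!r} maps to no protein")


@dataclass
class PeptideTable:
    records: list[PeptideRecord]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise QuantifyError("sample_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ProteinGroup:
    """A parsimony group: representative accession, absorbed members, peptides.

    ``unique_peptides`` are supporting peptides whose full protein mapping lies
    within this group's members.
    """

    representative: str
    members: frozenset[str]
    supporting_peptides: frozenset[str]
    unique_peptides: frozenset[str]


# ---------------------------------------------------------------------------
# peptide-level filters
# ---------------------------------------------------------------------------

def filter_peptides(
    table: PeptideTable, min_length: int = 7, min_score: float = 20.0
) -> PeptideTable:
    """Drop peptides shorter than ``min_length`` or scoring below ``min_score``.

    Both bounds are inclusive on the keep side (length >= 7, score >= 20);
    record order is preserved.
    """
    kept = [
        r
        for r in table.records
        if len(r.sequence) >= min_length and r.ion_score >= min_score
    ]
    return PeptideTable(records=kept, sample_ids=list(table.sample_ids))


# ---------------------------------------------------------------------------
# parsimony protein inference (greedy minimum set cover)
# ---------------------------------------------------------------------------

def infer_proteins_parsimony(table: PeptideTable) -> list[ProteinGroup]:
    """Explain every peptide with a minimum set of proteins (greedy cover).

    Greedy selection repeats until all peptides are covered, choosing the
    protein that covers the most uncovered peptides; ties break on the count
    of table-wide unique peptides (peptides mapping to that protein alone),
    then on the lexicographically smallest accession. Proteins whose peptide
    sets are subsets of a representative's are absorbed as group members, and
    every peptide is razor-assigned to exactly one group (its earliest-selected
    covering representative), so intensity is never counted twice.
    """
    pep_to_prot: dict[str, frozenset[str]] = {}
    for rec in table.records:
        if not rec.proteins:
            raise QuantifyError(f"peptide {rec.sequence!r} has an empty protein set")
        if rec.sequence in pep_to_prot:
            pep_to_prot[rec.sequence] = pep_to_prot[rec.sequence] | rec.proteins
        else:
            pep_to_prot[rec.sequence] = frozenset(rec.proteins)

    prot_to_pep: dict[str, set[str]] = {}
    for pep, prots in pep_to_prot.items():
        for p in prots:
            prot_to_pep.setdefault(p, set()).add(pep)

    n_unique = {
        p: sum(1 for pep in peps if len(pep_to_prot[pep]) == 1)
        for p, peps in prot_to_pep.items()
    }

    uncovered = set(pep_to_prot)
    representatives: list[str] = []
    while uncovered:
        best = min(
            prot_to_pep,
            key=lambda p: (-len(prot_to_pep[p] & uncovered), -n_unique[p], p),
        )
        gain = len(prot_to_pep[best] & uncovered)
        if gain == 0:  # pragma: no cover - unreachable: every peptide has a protein
            raise QuantifyError("set cover stalled")
        representatives.append(best)
        uncovered -= prot_to_pep[best]

    # absorb subset proteins into the representative with the largest overlap
    rep_set = set(representatives)
    members: dict[str, set[str]] = {r: {r} for r in representatives}
    for p, peps in prot_to_pep.items():
        if p in rep_set:
            continue
        candidates = [r for r in representatives if peps <= prot_to_pep[r]]
        if candidates:
            host = min(candidates, key=lambda r: (-len(prot_to_pep[r] & peps), r))
            members[host].add(p)

    # razor assignment: each peptide to its earliest-selected covering representative
    assigned: dict[str, str] = {}
    for rep in representatives:
        for pep in prot_to_pep[rep]:
            assigned.setdefault(pep, rep)

    groups = []
    for rep in sorted(representatives):
        mem = frozenset(members[rep])
        supporting = frozenset(p for p, r in assigned.items() if r == rep)
        unique = frozenset(p for p in supporting if pep_to_prot[p] <= mem)
        groups.append(
            ProteinGroup(
                representative=rep,
                members=mem,
                supporting_peptides=supporting,
                unique_peptides=unique,
            )
        )
    return groups


def filter_protein_groups(
    groups: list[ProteinGroup], min_unique_peptides: int = 2
) -> list[ProteinGroup]:
    """Keep groups supported by at least ``min_unique_peptides`` unique peptides."""
    return [g for g in groups if len(g.unique_peptides) >= min_unique_peptides]


# ---------------------------------------------------------------------------
# in silico tryptic digestion
# ---------------------------------------------------------------------------

_CLEAVAGE_KEIL = re.compile(r"(?<=[KR])(?!P)")
_CLEAVAGE_PLAIN = re.compile(r"(?<=[KR])")


def digest_tryptic(sequence: str, keil: bool = True) -> list[str]:
    """Fully tryptic fragments (zero missed cleavages) of ``sequence``.

    Cleaves C-terminal to K/R; with ``keil`` (default) cleavage is suppressed
    when the next residue is proline. Raises on non-standard residues, naming
    the first offending position (1-based).
    """
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise QuantifyError(
                f"non-standard residue {aa!r} at position {i + 1}"
            )
    pattern = _CLEAVAGE_KEIL if keil else _CLEAVAGE_PLAIN
    return [f for f in pattern.split(sequence) if f]


def count_theoretical_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30, keil: bool = True
) -> int:
    """Count tryptic fragments with ``min_len <= length <= max_len``."""
    if not sequence:
        raise QuantifyError("empty protein sequence")
    return sum(1 for f in digest_tryptic(sequence, keil=keil) if min_len <= len(f) <= max_len)


# ---------------------------------------------------------------------------
# iBAQ / FOT / imputation
# ---------------------------------------------------------------------------

def compute_ibaq(protein_intensity: float, n_theoretical: int) -> float:
    """iBAQ = summed peptide intensity / theoretically observable peptide count."""
    if n_theoretical < 1:
        raise QuantifyError(
            "protein not quantifiable: zero theoretically observable peptides"
        )
    return protein_intensity / n_theoretical


def normalize_fot(matrix: QuantMatrix) -> QuantMatrix:
    """Rescale each sample to fractions of total x1e5.

    Per sample, value_i -> value_i / sum_j(value_j) * 1e5 over observed values;
    each column of observed values then sums to 1e5 exactly.
    """
    if matrix.scale not in ("iBAQ", "intensity"):
        raise QuantifyError(f"FOT normalisation expects iBAQ input, got {matrix.scale!r}")
    totals = matrix.values.sum(axis=0, skipna=True)
    dead = [s for s, t in totals.items() if not t > 0]
    if dead:
        raise QuantifyError(f"all-zero or all-missing sample column(s): {dead}")
    values = matrix.values.div(totals, axis=1) * 1e5
    return QuantMatrix(values, "FOT", matrix.design)


def impute_missing(matrix: QuantMatrix) -> QuantMatrix:
    """Replace every missing cell with the global minimum observed value."""
    arr = matrix.values.to_numpy(dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise QuantifyError("cannot impute a fully missing matrix")
    return QuantMatrix(matrix.values.fillna(float(observed.min())), matrix.scale, matrix.design)


# ---------------------------------------------------------------------------
# end-to-end peptide table -> FOT matrix
# ---------------------------------------------------------------------------

def quantify_peptides(
    table: PeptideTable,
    sequences: dict[str, str],
    design: pd.DataFrame | None = None,
    min_length: int = 7,
    min_score: float = 20.0,
    min_unique_peptides: int = 2,
    theo_min_len: int = 7,
    theo_max_len: int = 30,
    keil: bool = True,
    impute: bool = True,
) -> tuple[QuantMatrix, dict]:
    """Run the full quantification chain on an identified-peptide table.

    Returns the protein x sample FOT matrix (imputed unless ``impute=False``)
    and a metadata dict logging the fixed stage order with per-stage counts.
    Representatives without a sequence in ``sequences`` or without theoretically
    observable peptides are dropped and recorded in the metadata.
    """
    meta: dict = {"stage_order": [
        "filter_peptides", "infer_proteins_parsimony", "filter_protein_groups",
        "sum_intensity", "compute_ibaq", "normalize_fot", "impute_missing",
    ]}
    filtered = filter_peptides(table, min_length=min_length, min_score=min_score)
    meta["n_peptides_input"] = len(table)
    meta["n_peptides_filtered"] = len(filtered)
    groups = infer_proteins_parsimony(filtered)
    meta["n_groups"] = len(groups)
    groups = filter_protein_groups(groups, min_unique_peptides=min_unique_peptides)
    meta["n_groups_min_unique"] = len(groups)

    by_seq: dict[str, list[PeptideRecord]] = {}
    for rec in filtered.records:
        by_seq.setdefault(rec.sequence, []).append(rec)

    dropped_no_seq, dropped_no_theo = [], []
    rows: dict[str, np.ndarray] = {}
    samples = list(table.sample_ids)
    for g in groups:
        seq = sequences.get(g.representative)
        if seq is None:
            dropped_no_seq.append(g.representative)
            continue
        n_theo = count_theoretical_peptides(seq, theo_min_len, theo_max_len, keil=keil)
        if n_theo == 0:
            dropped_no_theo.append(g.representative)
            continue
        total = np.full(len(samples), np.nan)
        for pep in g.supporting_peptides:
            for rec in by_seq.get(pep, []):
                for j, s in enumerate(samples):
                    v = rec.intensities.get(s)
                    if v is not None and not np.isnan(v):
                        total[j] = v if np.isnan(total[j]) else total[j] + v
        rows[g.representative] = np.array(
            [compute_ibaq(v, n_theo) if not np.isnan(v) else np.nan for v in total]
        )
    meta["dropped_no_sequence"] = sorted(dropped_no_seq)
    meta["dropped_no_theoretical_peptides"] = sorted(dropped_no_theo)
    if not rows:
        raise QuantifyError("no quantifiable protein groups")

    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples).sort_index()
    values.index.name = "feature"
    if design is None:
        design = make_design(samples, samples)
    ibaq = QuantMatrix(values, "iBAQ", design)
    fot = normalize_fot(ibaq)
    # column-sum invariant holds here, pre-imputation
    sums = fot.values.sum(axis=0, skipna=True)
    assert np.allclose(sums, 1e5, rtol=1e-6), "FOT column sums violated"
    meta["n_proteins_quantified"] = len(values)
    meta["imputed"] = bool(impute)
    return (impute_missing(fot) if impute else fot), meta
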