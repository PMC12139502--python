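"""End-to-end pipeline: simulate -> quantify -> signatures -> integrate ->
enrich -> crosstalk -> diff.

One :class:`PipelineConfig` holds every stage threshold (defaults: peptide
length >= 7, ion score >= 20, >= 2 unique peptides, 2x enhanced fold, 1.5x
ligand fold, median log10 FOT > -2 ubiquitous cut, 5% intercept tails, 3x
discordance factor, alpha 0.05) plus the synthetic-data generator settings.
All randomness flows from the single generator seed, so a rerun with the same
config reproduces byte-identical outputs; the run manifest records a content
hash over every written file to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crosstalk import (
    build_crosstalk_network,
    graph_from_edges,
    paths_to_frame,
    path_length_test,
    receptor_tf_path_lengths,
    write_graphml,
    write_sif,
)
from .differential import differential_expression
from .enrichment import ora_table
from .io import write_gene_list
from .quantify import impute_missing, quantify_peptides
from .rna_integration import (
    correlate_protein_rna,
    intercept_overrepresentation,
    pairs_from_matrices,
    ratio_discordance,
)
from .signatures import (
    call_enhanced_proteins,
    call_enriched_ligands,
    call_ubiquitous_proteins,
)
from .synthetic import GeneratorConfig, generate_atlas

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "signatures", "integrate", "enrich", "crosstalk", "diff")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stages: tuple[str, ...] = STAGES
    min_length: int = 7
    min_score: float = 20.0
    min_unique: int = 2
    enhanced_fold: float = 2.0
    ligand_fold: float = 1.5
    ubiquitous_log10: float = -2.0
    tail: float = 0.05
    discordance_factor: float = 3.0
    alpha: float = 0.05

    def validate(self) -> None:
        self.generator.validate()
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stage(s): {unknown}")
        for name in ("min_length", "min_score", "min_unique", "enhanced_fold",
                     "ligand_fold", "tail", "discordance_factor", "alpha"):
            if not getattr(self, name) > 0:
                raise PipelineError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _write_calls(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Outputs land in per-stage subdirectories of ``out_dir``. Any stage failure
    writes a manifest marking the failed stage (earlier outputs are kept) and
    re-raises as :class:`PipelineError`.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.generator.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    runners = {
        "simulate": _stage_simulate,
        "quantify": _stage_quantify,
        "signatures": _stage_signatures,
        "integrate": _stage_integrate,
        "enrich": _stage_enrich,
        "crosstalk": _stage_crosstalk,
        "diff": _stage_diff,
    }
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            stage_dir = out / stage
            stage_dir.mkdir(exist_ok=True)
            logger.info("stage %s", stage)
            try:
                rows = runners[stage](config, state, stage_dir)
            except Exception as exc:
                manifest["stages"].append(
                    {"name": stage, "status": "failed", "error": str(exc)}
                )
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": stage, "status": "completed", "rows": int(rows)}
            )
    finally:
        manifest["output_hash"] = _tree_hash(out)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    return manifest


def _tree_hash(root: Path) -> str:
    """Content hash over every output file (relative path + bytes)."""
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = generate_atlas(config.generator)
    atlas.write(out)
    state["atlas"] = atlas
    return config.generator.n_genes


def _stage_quantify(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = state["atlas"]
    fot, meta = quantify_peptides(
        atlas.peptide_table,
        atlas.fasta,
        design=atlas.celltype_proteome.design,
        min_length=config.min_length,
        min_score=config.min_score,
        min_unique_peptides=config.min_unique,
    )
    fot.to_tsv(out / "protein_fot.tsv")
    (out / "quantify_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    state["quantified"] = fot
    return len(fot.values)


def _stage_signatures(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = state["atlas"]
    celltype = impute_missing(atlas.celltype_proteome)
    region = impute_missing(atlas.region_proteome)
    state["celltype_imputed"] = celltype
    enhanced = call_enhanced_proteins(celltype, fold=config.enhanced_fold)
    ubiquitous = call_ubiquitous_proteins(region, threshold_log10=config.ubiquitous_log10)
    ligands = call_enriched_ligands(
        celltype, atlas.ligand_universe, fold=config.ligand_fold
    )
    _write_calls(enhanced, out / "enhanced.tsv")
    _write_calls(ubiquitous, out / "ubiquitous.tsv")
    _write_calls(ligands, out / "enriched_ligands.tsv")
    state["enhanced"] = enhanced
    state["ligand_calls"] = ligands
    return int(enhanced["passed"].sum() + ubiquitous["passed"].sum() + ligands["passed"].sum())


def _stage_integrate(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = state["atlas"]
    celltype = state.get("celltype_imputed") or impute_missing(atlas.celltype_proteome)
    profile = correlate_protein_rna(celltype, atlas.celltype_rna)
    profile.per_gene.to_csv(out / "spearman_per_gene.tsv", sep="\t", float_format="%.8g")
    profile.per_group.to_csv(out / "spearman_per_group.tsv", sep="\t", float_format="%.8g")
    rows = 0
    rank_rows = []
    observed = atlas.celltype_proteome.values.notna()
    for group in celltype.groups():
        detected = observed[atlas.celltype_proteome.samples_of(group)].any(axis=1)
        pairs = pairs_from_matrices(
            celltype, atlas.celltype_rna, group,
            features=detected.index[detected],
        )
        ranking = intercept_overrepresentation(pairs, tail=config.tail)
        for gene, dev in ranking.deviations.items():
            label = (
                "protein_over" if gene in ranking.protein_over
                else "rna_over" if gene in ranking.rna_over
                else ""
            )
            rank_rows.append(
                {"group": group, "feature": gene, "deviation": dev, "label": label}
            )
        rows += len(ranking.protein_over) + len(ranking.rna_over)
    pd.DataFrame(rank_rows).to_csv(
        out / "intercept_ranking.tsv", sep="\t", index=False, float_format="%.8g"
    )
    flags = ratio_discordance(
        celltype, atlas.celltype_rna, factor=config.discordance_factor
    )
    _write_calls(flags, out / "ratio_discordance.tsv")
    state["correlation_profile"] = profile
    return rows + int(flags["passed"].sum())


def _stage_enrich(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = state["atlas"]
    celltype = state.get("celltype_imputed") or impute_missing(atlas.celltype_proteome)
    universe = frozenset(celltype.values.index)
    enhanced = state["enhanced"]
    rows = 0
    for group in sorted(enhanced["group"].unique()):
        query = frozenset(
            enhanced.loc[(enhanced["group"] == group) & enhanced["passed"], "feature"]
        )
        if not query:
            continue
        table = ora_table(query, atlas.gene_sets, universe)
        table.to_csv(
            out / f"ora_enhanced_{group}.tsv", sep="\t", index=False, float_format="%.8g"
        )
        rows += len(table)
    return rows


def _stage_crosstalk(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = state["atlas"]
    celltype = state.get("celltype_imputed") or impute_missing(atlas.celltype_proteome)
    target = atlas.config.celltypes[0]  # the myocyte compartment receives the signal
    enhanced = state["enhanced"]
    universe = frozenset(celltype.values.index)
    # detection = observed (pre-imputation) in any replicate of the target cell-type
    observed = atlas.celltype_proteome.values[
        atlas.celltype_proteome.samples_of(target)
    ].notna().any(axis=1)
    detection = {target: frozenset(observed.index[observed])}
    enhanced_in_target = frozenset(
        enhanced.loc[(enhanced["group"] == target) & enhanced["passed"], "feature"]
    )
    cts_tfs = sorted(set(atlas.tfs) & enhanced_in_target)
    graph = graph_from_edges(atlas.pathway_edges)
    paths = build_crosstalk_network(
        ligand_calls=state["ligand_calls"],
        receptor_detection=detection,
        lr_pairs=atlas.lr_pairs,
        graph=graph,
        cts_tfs=cts_tfs,
        tftg=atlas.tftg_edges,
        pathway_sets=atlas.gene_sets,
        universe=universe | frozenset(graph.nodes),
        target_celltype=target,
        alpha=config.alpha,
    )
    frame = paths_to_frame(paths)
    frame.to_csv(out / "paths.tsv", sep="\t", index=False, float_format="%.8g")
    write_sif(paths, out / "network.sif")
    write_graphml(paths, out / "network.graphml")

    detected_tfs = sorted(set(atlas.tfs) & detection[target])
    receptors_used = sorted({p.receptor for p in paths}) or sorted(atlas.receptors)
    spec_tab, _ = receptor_tf_path_lengths(graph, receptors_used, cts_tfs)
    all_tab, _ = receptor_tf_path_lengths(graph, receptors_used, detected_tfs)
    summary: dict = {"n_paths": len(paths), "n_cts_tfs": len(cts_tfs)}
    if len(spec_tab) and len(all_tab):
        test = path_length_test(spec_tab["length"], all_tab["length"])
        summary.update(
            {
                "u_statistic": test.u_statistic,
                "p_value": test.p_value,
                "method": test.method,
                "n_specific": test.n,
                "n_all": test.m,
                "median_specific": float(spec_tab["length"].median()),
                "median_all": float(all_tab["length"].median()),
            }
        )
        state["path_test"] = test
    (out / "path_test.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return len(paths)


def _stage_diff(config: PipelineConfig, state: dict, out: Path) -> int:
    atlas = state["atlas"]
    matrix = impute_missing(atlas.case_control_proteome)
    design = matrix.design
    rows = 0
    results = {}
    for region in atlas.config.case_regions:
        case = list(design.index[(design["region"] == region) & (design["condition"] == "DCM")])
        control = list(design.index[(design["region"] == region) & (design["condition"] == "AUM")])
        res = differential_expression(matrix, case, control, alpha=config.alpha)
        res.to_csv(out / f"diff_{region}.tsv", sep="\t", float_format="%.8g")
        up = res.index[res["significant"] & (res["log2fc"] > 0)]
        down = res.index[res["significant"] & (res["log2fc"] < 0)]
        write_gene_list(up, out / f"up_{region}.txt")
        write_gene_list(down, out / f"down_{region}.txt")
        rows += int(res["significant"].sum())
        results[region] = res
    state["differential"] = results
    return rows
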