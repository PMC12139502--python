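"""Synthetic multi-omic atlas generator with planted ground truth.

The generator emulates the statistical structure of a cell-type- and
region-resolved heart multi-omics study so every downstream stage has a
self-contained test surface:

* a **cell-type proteome** (default 4 cell-types CM/CF/EC/IM x 3 replicates)
  with disjoint planted marker sets per cell-type (multiplicative
  ``marker_fold`` on a lognormal baseline spanning many orders of magnitude);
* a matched **cell-type transcriptome** (FPKM) whose gene-level abundances are
  coupled to the proteome through a Gaussian copula on the log scale, with the
  latent correlation chosen analytically so the realised Spearman rank
  correlation across genes matches ``rna_coupling``;
* planted **discordant genes** carrying a constant protein-only or RNA-only
  log2 offset (protein-high / rna-high);
* a **region proteome** (default 6 regions x 3 replicates) with per-region
  planted markers;
* a **case/control proteome** (4 regions x 2 conditions x ``n_case_samples``)
  with per-region planted up/down effects of ``case_effect_fold``;
* **interaction networks** (ligand-receptor pairs, a connected pathway graph,
  TF->target-gene edges) in which a designated TF subset is wired
  ``short_bias`` edges closer to the receptors than the rest — the alternative
  hypothesis for the shortest-path statistic; an empty planted set yields
  fully exchangeable TF distances (the null);
* an **identified-peptide table** plus protein FASTA whose tryptic peptide
  intensities sum to the planted protein intensities up to lognormal noise,
  salted with short, low-score and shared junk peptides to exercise the
  filtering and parsimony stages.

Replicate noise is lognormal with coefficient of variation ``noise_cv``.
Values below the ``detection_quantile`` of each matrix are dropped
(left-censoring) to mimic label-free dropout, so the global-minimum imputation
rule is exercised. Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import io as catio
from .matrix import QuantMatrix, make_design
from .quantify import PeptideRecord, PeptideTable, digest_tryptic

__all__ = [
    "GeneratorConfig",
    "TruthLabels",
    "SyntheticAtlas",
    "generate_atlas",
    "generate_networks",
    "generate_peptides",
    "latent_copula_rho",
]

CELLTYPE_LABELS = ("CM", "CF", "EC", "IM")
REGION_LABELS = ("LA", "RA", "LV", "RV", "CP", "PF")
CONDITIONS = ("DCM", "AUM")

# residues used for synthetic tryptic blocks: no K/R (internal cleavage) and
# no P (Keil suppression), so each block is exactly one theoretical peptide
_BLOCK_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))


class ConfigError(ValueError):
    """Raised when a GeneratorConfig field is invalid; names the field."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic atlas; defaults are the study conditions."""

    n_genes: int = 2000
    n_celltypes: int = 4
    n_regions: int = 6
    n_replicates: int = 3
    marker_fraction: float = 0.05
    marker_fold: float = 4.0
    ligand_fold: float = 3.0
    n_ligands_per_celltype: int = 6
    n_decoy_ligands: int = 12
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    rna_log_mean: float = 1.0
    rna_log_sd: float = 1.5
    noise_cv: float = 0.1
    rna_coupling: float = 0.48
    discordant_fraction: float = 0.05  # per direction (protein-high, rna-high)
    discordant_offset_log2: float = 3.0
    case_effect_fold: float = 2.0
    case_fraction: float = 0.05
    n_case_samples: int = 12
    detection_quantile: float = 0.05
    # network structure
    n_receptors: int = 12
    n_tfs: int = 30
    n_intermediates: int = 60
    n_planted_short_tfs: int = 8
    tf_chain_length: int = 3
    short_bias: int = 2
    edge_prob: float = 0.03
    n_tf_anchors: int = 2  # pathway-graph attachment points per TF chain
    # peptide surface
    peptides_per_protein: tuple[int, int] = (4, 9)
    shared_peptide_fraction: float = 0.05
    short_peptide_fraction: float = 0.05
    low_score_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_celltypes", "n_regions", "n_replicates",
                     "n_case_samples", "n_receptors", "n_tfs", "n_intermediates",
                     "tf_chain_length"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("marker_fold", "ligand_fold", "case_effect_fold"):
            if not getattr(self, name) > 1:
                raise ConfigError(f"{name} must be > 1")
        if not 0 < self.marker_fraction < 1:
            raise ConfigError("marker_fraction must be in (0, 1)")
        if self.marker_fraction * self.n_celltypes > 1:
            raise ConfigError("marker_fraction: disjoint marker sets exceed the gene pool")
        for name in ("discordant_fraction", "case_fraction", "detection_quantile",
                     "shared_peptide_fraction", "short_peptide_fraction",
                     "low_score_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in [0, 1)")
        if not self.noise_cv > 0:
            raise ConfigError("noise_cv must be > 0")
        if not 0 < self.rna_coupling < 1:
            raise ConfigError("rna_coupling must be in (0, 1)")
        if not 0 <= self.n_planted_short_tfs <= self.n_tfs:
            raise ConfigError("n_planted_short_tfs must be in [0, n_tfs]")
        if not 0 <= self.short_bias < self.tf_chain_length + 1:
            raise ConfigError("short_bias must be in [0, tf_chain_length]")
        if not 0 < self.edge_prob < 1:
            raise ConfigError("edge_prob must be in (0, 1)")
        if not 1 <= self.n_tf_anchors <= self.n_intermediates:
            raise ConfigError("n_tf_anchors must be in [1, n_intermediates]")
        lo, hi = self.peptides_per_protein
        if not 2 <= lo <= hi:
            raise ConfigError("peptides_per_protein must satisfy 2 <= lo <= hi")
        if int(self.seed) < 0:
            raise ConfigError("seed must be a non-negative integer")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peptides_per_protein"] = list(self.peptides_per_protein)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "peptides_per_protein" in d:
            d["peptides_per_protein"] = tuple(d["peptides_per_protein"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived labels ----------------------------------------------------
    @property
    def celltypes(self) -> tuple[str, ...]:
        if self.n_celltypes == len(CELLTYPE_LABELS):
            return CELLTYPE_LABELS
        return tuple(f"CT{i + 1}" for i in range(self.n_celltypes))

    @property
    def regions(self) -> tuple[str, ...]:
        if self.n_regions <= len(REGION_LABELS):
            return REGION_LABELS[: self.n_regions]
        return tuple(f"RG{i + 1}" for i in range(self.n_regions))

    @property
    def case_regions(self) -> tuple[str, ...]:
        return self.regions[: min(4, self.n_regions)]

    @property
    def noise_log10_sd(self) -> float:
        """Lognormal replicate noise on the log10 scale for the given CV."""
        return math.sqrt(math.log1p(self.noise_cv**2)) / math.log(10)


@dataclass
class TruthLabels:
    """Every planted signal, for recovery scoring."""

    planted_markers: dict[str, frozenset[str]]
    planted_region_markers: dict[str, frozenset[str]]
    planted_ligands: dict[str, frozenset[str]]
    planted_discordant: dict[str, str]  # gene -> "protein-high" | "rna-high"
    planted_de: dict[tuple[str, str], frozenset[str]]  # (region, "up"/"down") -> genes
    planted_short_tfs: frozenset[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_markers": {k: sorted(v) for k, v in self.planted_markers.items()},
            "planted_region_markers": {
                k: sorted(v) for k, v in self.planted_region_markers.items()
            },
            "planted_ligands": {k: sorted(v) for k, v in self.planted_ligands.items()},
            "planted_discordant": dict(sorted(self.planted_discordant.items())),
            "planted_de": {
                f"{r}:{d}": sorted(v) for (r, d), v in sorted(self.planted_de.items())
            },
            "planted_short_tfs": sorted(self.planted_short_tfs),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


@dataclass
class SyntheticAtlas:
    config: GeneratorConfig
    peptide_table: PeptideTable
    celltype_proteome: QuantMatrix
    region_proteome: QuantMatrix
    case_control_proteome: QuantMatrix
    celltype_rna: QuantMatrix
    fasta: dict[str, str]
    lr_pairs: pd.DataFrame
    pathway_edges: pd.DataFrame
    tftg_edges: pd.DataFrame
    gene_sets: catio.GeneSetCollection
    truth: TruthLabels
    ligand_universe: tuple[str, ...] = ()
    receptors: tuple[str, ...] = ()
    tfs: tuple[str, ...] = ()

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        catio.write_peptide_table(self.peptide_table, out / "peptides.tsv")
        self.celltype_proteome.to_tsv(out / "celltype_fot.tsv")
        self.region_proteome.to_tsv(out / "region_fot.tsv")
        self.case_control_proteome.to_tsv(out / "case_control_fot.tsv")
        self.celltype_rna.to_tsv(out / "celltype_fpkm.tsv")
        catio.write_fasta(self.fasta, out / "proteins.fasta")
        catio.write_edges(self.lr_pairs, out / "lr_pairs.tsv")
        catio.write_edges(self.pathway_edges, out / "pathway_edges.tsv")
        catio.write_edges(self.tftg_edges, out / "tftg_edges.tsv")
        catio.write_gmt(self.gene_sets, out / "gene_sets.gmt")
        self.truth.to_json(out / "truth.json")
        self.config.to_yaml(out / "config.yaml")
        catio.write_gene_list(self.ligand_universe, out / "ligand_universe.txt")
        catio.write_gene_list(self.receptors, out / "receptors.txt")
        catio.write_gene_list(self.tfs, out / "tfs.txt")


# ---------------------------------------------------------------------------
# copula calibration
# ---------------------------------------------------------------------------

def latent_copula_rho(spearman_target: float) -> float:
    """Latent Gaussian correlation giving the target large-sample Spearman.

    For a bivariate normal, rho_s = (6/pi) * asin(rho/2); inverting gives the
    latent rho to feed the copula.
    """
    return 2.0 * math.sin(math.pi * spearman_target / 6.0)


# ---------------------------------------------------------------------------
# atlas generation
# ---------------------------------------------------------------------------

def _censor(values: np.ndarray, quantile: float) -> np.ndarray:
    """Left-censor: values below the matrix-wide detection quantile become NaN."""
    if quantile <= 0:
        return values
    thr = np.quantile(values, quantile)
    out = values.copy()
    out[out < thr] = np.nan
    return out


def _fot(values: np.ndarray) -> np.ndarray:
    """Column-wise fraction-of-total x1e5 over observed values."""
    totals = np.nansum(values, axis=0)
    return values / totals * 1e5


def _matrix(
    log10_values: np.ndarray,
    gene_ids: list[str],
    samples: list[str],
    design: pd.DataFrame,
    quantile: float,
) -> QuantMatrix:
    intens = 10.0 ** log10_values
    fot = _fot(_censor(intens, quantile))
    df = pd.DataFrame(fot, index=pd.Index(gene_ids, name="feature"), columns=samples)
    return QuantMatrix(df, "FOT", design)


def generate_atlas(config: GeneratorConfig) -> SyntheticAtlas:
    """Generate the full synthetic atlas; deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    genes = [f"G{i:0{width}d}" for i in range(1, n + 1)]

    # ---- role assignment from one shuffled pool --------------------------
    pool = [genes[i] for i in rng.permutation(n)]
    cursor = 0

    def take(k: int, what: str) -> list[str]:
        nonlocal cursor
        if cursor + k > len(pool):
            raise ConfigError(
                f"n_genes too small: gene pool exhausted while assigning {what}"
            )
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    k_marker = int(round(config.marker_fraction * n))
    celltypes = list(config.celltypes)
    regions = list(config.regions)
    markers = {ct: take(k_marker, "cell-type markers") for ct in celltypes}
    region_markers = {rg: take(k_marker, "region markers") for rg in regions}
    ligands = {
        ct: take(config.n_ligands_per_celltype, "ligands") for ct in celltypes
    }
    decoy_ligands = take(config.n_decoy_ligands, "decoy ligands")
    k_disc = int(round(config.discordant_fraction * n))
    protein_high = take(k_disc, "protein-high discordant genes")
    rna_high = take(k_disc, "rna-high discordant genes")

    n_short = min(config.n_planted_short_tfs, len(markers[celltypes[0]]))
    planted_short = sorted(markers[celltypes[0]])[:n_short]  # ctsTFs of the first cell-type
    other_tfs = take(config.n_tfs - n_short, "transcription factors")
    tfs = sorted(planted_short) + other_tfs
    receptors = take(config.n_receptors, "receptors")
    intermediates = take(config.n_intermediates, "pathway intermediates")
    chain_pool = take(
        max(0, (config.tf_chain_length - 1) * config.n_tfs), "pathway chain nodes"
    )

    # ---- gene-level baselines (Gaussian copula on log10 scale) -----------
    # The latent baseline is truncated at +-3 sd: with sd 1.5 (log10) that
    # spans the ~9 orders of magnitude a deep proteome covers, and it keeps a
    # single protein from dominating a sample's total mass — an unbounded
    # tail at this gene count would turn FOT columns into near single-protein
    # ratios and correlate every downstream test statistic.
    rho = latent_copula_rho(config.rna_coupling)
    z1 = truncnorm.ppf(rng.random(n), -3.0, 3.0)
    z2 = rng.standard_normal(n)
    mu_p = config.baseline_log_mean + config.baseline_log_sd * z1
    mu_r = config.rna_log_mean + config.rna_log_sd * (
        rho * z1 + math.sqrt(1.0 - rho**2) * z2
    )

    gene_index = {g: i for i, g in enumerate(genes)}
    d_off = config.discordant_offset_log2 * math.log10(2.0)
    mu_p = mu_p.copy()
    mu_p[[gene_index[g] for g in protein_high]] += d_off
    mu_r[[gene_index[g] for g in rna_high]] += d_off

    # ---- cell-type effects (markers and ligands, protein and RNA) --------
    eff_ct = np.zeros((n, len(celltypes)))
    for j, ct in enumerate(celltypes):
        eff_ct[[gene_index[g] for g in markers[ct]], j] += math.log10(config.marker_fold)
        eff_ct[[gene_index[g] for g in ligands[ct]], j] += math.log10(config.ligand_fold)

    sigma = config.noise_log10_sd
    reps = range(1, config.n_replicates + 1)

    ct_samples = [f"{ct}_{r}" for ct in celltypes for r in reps]
    ct_design = make_design(
        ct_samples,
        groups=[s.rsplit("_", 1)[0] for s in ct_samples],
        replicates=[int(s.rsplit("_", 1)[1]) for s in ct_samples],
    )
    ct_log = np.column_stack(
        [
            mu_p + eff_ct[:, j] + sigma * rng.standard_normal(n)
            for j, _ct in enumerate(celltypes)
            for _r in reps
        ]
    )
    celltype_proteome = _matrix(
        ct_log, genes, ct_samples, ct_design, config.detection_quantile
    )

    # ---- matched transcriptome (FPKM; no dropout) ------------------------
    rna_log = np.column_stack(
        [
            mu_r + eff_ct[:, j] + sigma * rng.standard_normal(n)
            for j, _ct in enumerate(celltypes)
            for _r in reps
        ]
    )
    celltype_rna = QuantMatrix(
        pd.DataFrame(
            10.0 ** rna_log, index=pd.Index(genes, name="feature"), columns=ct_samples
        ),
        "FPKM",
        ct_design,
    )

    # ---- region proteome -------------------------------------------------
    eff_rg = np.zeros((n, len(regions)))
    for j, rg in enumerate(regions):
        eff_rg[[gene_index[g] for g in region_markers[rg]], j] += math.log10(
            config.marker_fold
        )
    rg_samples = [f"{rg}_{r}" for rg in regions for r in reps]
    rg_design = make_design(
        rg_samples,
        groups=[s.rsplit("_", 1)[0] for s in rg_samples],
        replicates=[int(s.rsplit("_", 1)[1]) for s in rg_samples],
    )
    rg_log = np.column_stack(
        [
            mu_p + eff_rg[:, j] + sigma * rng.standard_normal(n)
            for j, _rg in enumerate(regions)
            for _r in reps
        ]
    )
    region_proteome = _matrix(
        rg_log, genes, rg_samples, rg_design, config.detection_quantile
    )

    # ---- case/control proteome -------------------------------------------
    case_regions = list(config.case_regions)
    k_case = int(round(config.case_fraction * n))
    planted_de: dict[tuple[str, str], frozenset[str]] = {}
    cc_cols, cc_groups, cc_regions_col, cc_cond, cc_rep, cc_log = [], [], [], [], [], []
    log_fold = math.log10(config.case_effect_fold)
    for j, rg in enumerate(case_regions):
        if k_case:
            picked = rng.choice(n, size=k_case, replace=False)
            up = [genes[i] for i in picked[: k_case // 2 + k_case % 2]]
            down = [genes[i] for i in picked[k_case // 2 + k_case % 2 :]]
        else:
            up, down = [], []
        planted_de[(rg, "up")] = frozenset(up)
        planted_de[(rg, "down")] = frozenset(down)
        cond_eff = np.zeros(n)
        cond_eff[[gene_index[g] for g in up]] += log_fold
        cond_eff[[gene_index[g] for g in down]] -= log_fold
        for cond in CONDITIONS:
            eff = cond_eff if cond == "DCM" else 0.0
            for i in range(1, config.n_case_samples + 1):
                cc_cols.append(f"{rg}_{cond}_{i:02d}")
                cc_groups.append(f"{rg}_{cond}")
                cc_regions_col.append(rg)
                cc_cond.append(cond)
                cc_rep.append(i)
                cc_log.append(mu_p + eff_rg[:, j] + eff + sigma * rng.standard_normal(n))
    cc_design = make_design(
        cc_cols, groups=cc_groups, replicates=cc_rep,
        region=cc_regions_col, condition=cc_cond,
    )
    case_control_proteome = _matrix(
        np.column_stack(cc_log), genes, cc_cols, cc_design, config.detection_quantile
    )

    # ---- networks ---------------------------------------------------------
    net = generate_networks(
        config,
        planted_short_tfs=planted_short,
        ligands=sorted(set().union(*(ligands[ct] for ct in celltypes)) | set(decoy_ligands)),
        receptors=receptors,
        tfs=tfs,
        intermediates=intermediates,
        chain_pool=chain_pool,
        tg_pool=genes,
        rng=rng,
    )

    # ---- gene sets (markers + planted pathways + random decoys) ----------
    sets: dict[str, frozenset[str]] = {}
    for ct in celltypes:
        sets[f"MARKERS_{ct}"] = frozenset(markers[ct])
    sets.update(net["pathway_sets"].sets)
    for i in range(5):
        sets[f"RANDOM_{i + 1}"] = frozenset(
            genes[j] for j in rng.choice(n, size=25, replace=False)
        )
    gene_sets = catio.GeneSetCollection(sets, source="synthetic")

    # ---- peptide surface --------------------------------------------------
    fasta = _build_fasta(genes, config, rng)
    # planted per-sample intensities (censored), on the linear scale
    planted_intensity = pd.DataFrame(
        _censor(10.0 ** ct_log, config.detection_quantile),
        index=pd.Index(genes, name="feature"),
        columns=ct_samples,
    )
    peptide_table = generate_peptides(fasta, planted_intensity, config, rng=rng)

    truth = TruthLabels(
        planted_markers={ct: frozenset(markers[ct]) for ct in celltypes},
        planted_region_markers={rg: frozenset(region_markers[rg]) for rg in regions},
        planted_ligands={ct: frozenset(ligands[ct]) for ct in celltypes},
        planted_discordant={
            **{g: "protein-high" for g in protein_high},
            **{g: "rna-high" for g in rna_high},
        },
        planted_de=planted_de,
        planted_short_tfs=frozenset(planted_short),
    )
    return SyntheticAtlas(
        config=config,
        peptide_table=peptide_table,
        celltype_proteome=celltype_proteome,
        region_proteome=region_proteome,
        case_control_proteome=case_control_proteome,
        celltype_rna=celltype_rna,
        fasta=fasta,
        lr_pairs=net["lr_pairs"],
        pathway_edges=net["pathway_edges"],
        tftg_edges=net["tftg_edges"],
        gene_sets=gene_sets,
        truth=truth,
        ligand_universe=tuple(
            sorted(set().union(*(ligands[ct] for ct in celltypes)) | set(decoy_ligands))
        ),
        receptors=tuple(receptors),
        tfs=tuple(tfs),
    )


def enhanced_truth(atlas: SyntheticAtlas, fold: float = 2.0) -> dict[str, set[tuple[str, str]]]:
    """Ground-truth (gene, cell-type) pairs for scoring enhanced-protein calls.

    ``expected`` holds every planted enhancement whose fold reaches the rule
    threshold — cell-type markers always, planted ligands when ``ligand_fold``
    >= fold (a 3x ligand is genuinely cell-type-enhanced, not a false
    positive). ``recoverable`` restricts the marker set to genes observed in
    at least one replicate of their own cell-type: a protein censored below
    detection everywhere was never identified and no rule can recall it.
    """
    cfg = atlas.config
    expected: set[tuple[str, str]] = set()
    for ct, genes in atlas.truth.planted_markers.items():
        expected |= {(g, ct) for g in genes}
    if cfg.ligand_fold >= fold:
        for ct, genes in atlas.truth.planted_ligands.items():
            expected |= {(g, ct) for g in genes}
    observed = atlas.celltype_proteome.values.notna()
    recoverable: set[tuple[str, str]] = set()
    for ct, genes in atlas.truth.planted_markers.items():
        cols = atlas.celltype_proteome.samples_of(ct)
        seen = observed[cols].any(axis=1)
        recoverable |= {(g, ct) for g in genes if bool(seen.get(g, False))}
    return {"expected": expected, "recoverable_markers": recoverable}


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def generate_networks(
    config: GeneratorConfig,
    planted_short_tfs,
    ligands: list[str] | None = None,
    receptors: list[str] | None = None,
    tfs: list[str] | None = None,
    intermediates: list[str] | None = None,
    chain_pool: list[str] | None = None,
    tg_pool: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Build ligand-receptor pairs, a connected pathway graph and TF->TG edges.

    Every TF hangs off a random pathway-graph anchor through a private chain of
    ``tf_chain_length`` edges; TFs in ``planted_short_tfs`` use a chain
    shortened by ``short_bias`` edges (floor 1), which makes their receptor
    distances stochastically smaller. With an empty planted set all TFs are
    constructed identically, so distances are exchangeable (the null).

    Returns a dict with ``lr_pairs``, ``pathway_edges``, ``tftg_edges``
    DataFrames plus the ``graph`` (networkx), ``pathway_sets`` collection and
    the node role lists.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if receptors is None:
        receptors = [f"R{i:03d}" for i in range(1, config.n_receptors + 1)]
    if tfs is None:
        tfs = [f"T{i:03d}" for i in range(1, config.n_tfs + 1)]
    if intermediates is None:
        intermediates = [f"N{i:03d}" for i in range(1, config.n_intermediates + 1)]
    if chain_pool is None:
        chain_pool = [
            f"C{i:03d}" for i in range(1, (config.tf_chain_length - 1) * config.n_tfs + 1)
        ]
    if ligands is None:
        ligands = [f"L{i:03d}" for i in range(1, config.n_receptors + 1)]
    planted_short_tfs = sorted(set(planted_short_tfs))
    unknown = [t for t in planted_short_tfs if t not in set(tfs)]
    if unknown:
        raise ConfigError(f"planted short TF(s) not in the TF node set: {unknown[:5]}")

    g = nx.Graph()
    g.add_nodes_from(intermediates)
    # random spanning tree keeps the graph connected
    for i in range(1, len(intermediates)):
        j = int(rng.integers(0, i))
        g.add_edge(intermediates[i], intermediates[j], pathway="BACKBONE")
    # extra random edges for realistic shortcuts
    for i in range(len(intermediates)):
        for j in range(i + 1, len(intermediates)):
            if rng.random() < config.edge_prob:
                g.add_edge(intermediates[i], intermediates[j], pathway="BACKBONE")

    for r in receptors:
        anchor = intermediates[int(rng.integers(0, len(intermediates)))]
        g.add_edge(r, anchor, pathway="BACKBONE")
        if rng.random() < 0.5 and len(intermediates) > 1:
            g.add_edge(
                r, intermediates[int(rng.integers(0, len(intermediates)))],
                pathway="BACKBONE",
            )

    pathway_sets: dict[str, frozenset[str]] = {}
    chain_cursor = 0
    planted = set(planted_short_tfs)
    for tf in tfs:
        length = config.tf_chain_length - (config.short_bias if tf in planted else 0)
        length = max(1, length)
        chain: list[str] = []
        for _ in range(length - 1):
            if chain_cursor >= len(chain_pool):
                raise ConfigError("chain_pool too small for the requested TF chains")
            chain.append(chain_pool[chain_cursor])
            chain_cursor += 1
        nodes = [*chain, tf]
        # the chain head hangs off several random anchors; the min over anchors
        # decorrelates a TF's distances to different receptors, keeping the
        # null path-length distribution exchangeable rather than clustered
        k_anchor = min(config.n_tf_anchors, len(intermediates))
        anchors = [
            intermediates[int(i)]
            for i in rng.choice(len(intermediates), size=k_anchor, replace=False)
        ]
        for anchor in anchors:
            g.add_edge(anchor, nodes[0], pathway=f"PW_{tf}")
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b, pathway=f"PW_{tf}")
        pathway_sets[f"PW_{tf}"] = frozenset([*anchors, *nodes])

    n_pairs_each = 2
    lr_rows = []
    for lig in ligands:
        chosen = rng.choice(len(receptors), size=min(n_pairs_each, len(receptors)), replace=False)
        for idx in sorted(int(i) for i in chosen):
            lr_rows.append({"ligand": lig, "receptor": receptors[idx]})
    lr_pairs = pd.DataFrame(lr_rows, columns=["ligand", "receptor"])

    if tg_pool is None:
        tg_pool = [f"TG{i:03d}" for i in range(1, 201)]
    tg_rows = []
    for tf in tfs:
        k = int(rng.integers(5, 16))
        chosen = rng.choice(len(tg_pool), size=min(k, len(tg_pool)), replace=False)
        for idx in sorted(int(i) for i in chosen):
            if tg_pool[idx] != tf:
                tg_rows.append({"tf": tf, "target": tg_pool[idx]})
    tftg_edges = pd.DataFrame(tg_rows, columns=["tf", "target"])

    pathway_edges = pd.DataFrame(
        [
            {"a": a, "b": b, "pathway": data.get("pathway", "")}
            for a, b, data in sorted(g.edges(data=True))
        ],
        columns=["a", "b", "pathway"],
    )
    return {
        "lr_pairs": lr_pairs,
        "pathway_edges": pathway_edges,
        "tftg_edges": tftg_edges,
        "graph": g,
        "pathway_sets": catio.GeneSetCollection(dict(pathway_sets), source="synthetic"),
        "receptors": list(receptors),
        "tfs": list(tfs),
        "intermediates": list(intermediates),
    }


# ---------------------------------------------------------------------------
# peptide surface
# ---------------------------------------------------------------------------

def _build_fasta(
    proteins: list[str], config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Synthetic protein sequences assembled from tryptic blocks.

    Each block is 7-14 non-K/R/P residues ending in K or R, so a fully tryptic
    digest recovers exactly the blocks, all within the 7-30 iBAQ length bounds.
    """
    lo, hi = config.peptides_per_protein
    out: dict[str, str] = {}
    for acc in proteins:
        n_blocks = int(rng.integers(lo, hi + 1))
        blocks = []
        for _ in range(n_blocks):
            length = int(rng.integers(7, 15))
            body = "".join(rng.choice(_BLOCK_ALPHABET, size=length - 1))
            blocks.append(body + ("K" if rng.random() < 0.5 else "R"))
        out[acc] = "".join(blocks)
    return out


def generate_peptides(
    fasta: dict[str, str],
    protein_abundances: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> PeptideTable:
    """Identified-peptide table whose intensities sum to the planted proteins.

    Per protein and sample, the planted intensity is split over the protein's
    in-bounds tryptic peptides with Dirichlet weights and multiplied by
    lognormal noise (CV = ``noise_cv``), so summing peptides recovers the
    protein up to noise. Proteins with no positive abundance in any sample
    (decoys) are absent from the table. Junk records — short (<7 aa),
    low-score (<20) and two-protein shared peptides — are appended at the
    configured fractions to exercise the filters and the parsimony stage.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    missing = [p for p in protein_abundances.index if p not in fasta]
    if missing:
        raise ConfigError(
            f"protein(s) in abundances missing from fasta: {missing[:5]}"
        )
    samples = list(protein_abundances.columns)
    sigma_ln = math.sqrt(math.log1p(config.noise_cv**2))
    records: list[PeptideRecord] = []
    quantified: list[str] = []
    for acc in protein_abundances.index:
        row = protein_abundances.loc[acc].to_numpy(dtype=float)
        if not np.any(np.nan_to_num(row) > 0):
            continue  # zero/absent protein leaves no peptides
        peptides = [
            p for p in digest_tryptic(fasta[acc]) if 7 <= len(p) <= 30
        ]
        if not peptides:
            raise ConfigError(f"protein {acc} has no in-bounds tryptic peptides")
        quantified.append(acc)
        weights = rng.dirichlet(np.full(len(peptides), 5.0))
        noise = np.exp(sigma_ln * rng.standard_normal((len(peptides), len(samples))))
        for i, pep in enumerate(peptides):
            intens = {
                s: float(row[j] * weights[i] * noise[i, j])
                for j, s in enumerate(samples)
                if np.isfinite(row[j]) and row[j] > 0
            }
            records.append(
                PeptideRecord(
                    sequence=pep,
                    proteins=frozenset([acc]),
                    ion_score=float(rng.uniform(30.0, 110.0)),
                    intensities=intens,
                )
            )

    n_real = len(records)
    mean_intens = float(
        np.nanmean(protein_abundances.to_numpy(dtype=float))
    ) if n_real else 1.0

    def _junk_sequence(length: int) -> str:
        return "".join(rng.choice(_BLOCK_ALPHABET, size=length))

    for _ in range(int(round(config.short_peptide_fraction * n_real))):
        acc = quantified[int(rng.integers(0, len(quantified)))]
        records.append(
            PeptideRecord(
                sequence=_junk_sequence(int(rng.integers(4, 7))),
                proteins=frozenset([acc]),
                ion_score=float(rng.uniform(30.0, 110.0)),
                intensities={s: float(mean_intens * 0.01) for s in samples},
            )
        )
    for _ in range(int(round(config.low_score_fraction * n_real))):
        acc = quantified[int(rng.integers(0, len(quantified)))]
        records.append(
            PeptideRecord(
                sequence=_junk_sequence(int(rng.integers(8, 13))),
                proteins=frozenset([acc]),
                ion_score=float(rng.uniform(5.0, 19.5)),
                intensities={s: float(mean_intens * 0.01) for s in samples},
            )
        )
    if config.shared_peptide_fraction > 0 and len(quantified) >= 2:
        for _ in range(int(round(config.shared_peptide_fraction * n_real))):
            i, j = rng.choice(len(quantified), size=2, replace=False)
            records.append(
                PeptideRecord(
                    sequence=_junk_sequence(int(rng.integers(8, 13))),
                    proteins=frozenset([quantified[int(i)], quantified[int(j)]]),
                    ion_score=float(rng.uniform(30.0, 110.0)),
                    intensities={s: float(mean_intens * 0.001) for s in samples},
                )
            )
    return PeptideTable(records=records, sample_ids=samples)
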