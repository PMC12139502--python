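"""Synthetic atlas generator: determinism, planted structure, networks, peptides."""

import numpy as np
import pandas as pd
import pytest

from cardatlas import GeneratorConfig, generate_atlas
from cardatlas.quantify import filter_peptides, infer_proteins_parsimony
from cardatlas.synthetic import (
    ConfigError,
    generate_networks,
    generate_peptides,
    latent_copula_rho,
)
from cardatlas.crosstalk import receptor_tf_path_lengths, path_length_test


SMALL = dict(
    n_genes=300, n_ligands_per_celltype=2, n_decoy_ligands=4,
    n_receptors=5, n_tfs=8, n_intermediates=12, n_planted_short_tfs=2,
)


def test_config_validation_names_offending_field():
    with pytest.raises(ConfigError, match="marker_fold"):
        GeneratorConfig(marker_fold=1.0).validate()
    with pytest.raises(ConfigError, match="marker_fraction"):
        GeneratorConfig(marker_fraction=0.3, n_celltypes=4).validate()
    with pytest.raises(ConfigError, match="noise_cv"):
        GeneratorConfig(noise_cv=0.0).validate()
    GeneratorConfig(case_fraction=0.0).validate()  # null configuration is legal


def test_atlas_determinism_byte_identical(tmp_path):
    cfg = GeneratorConfig(seed=5, **SMALL)
    a = generate_atlas(cfg)
    b = generate_atlas(GeneratorConfig(seed=5, **SMALL))
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*"))
    files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*"))
    assert files_a == files_b
    for rel in files_a:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes(), rel


def test_different_seed_changes_output():
    a = generate_atlas(GeneratorConfig(seed=1, **SMALL))
    b = generate_atlas(GeneratorConfig(seed=2, **SMALL))
    assert not a.celltype_proteome.values.equals(b.celltype_proteome.values)


def test_marker_counts_exact_and_disjoint():
    cfg = GeneratorConfig(seed=0, n_genes=1000, marker_fraction=0.05,
                          n_ligands_per_celltype=2, n_decoy_ligands=4,
                          n_receptors=5, n_tfs=8, n_intermediates=12,
                          n_planted_short_tfs=2)
    atlas = generate_atlas(cfg)
    sets = list(atlas.truth.planted_markers.values())
    assert all(len(s) == 50 for s in sets)
    for i, s in enumerate(sets):
        for t in sets[i + 1:]:
            assert not (s & t)


def test_identifier_consistency_across_components(default_atlas):
    atlas = default_atlas
    genes = set(atlas.celltype_proteome.values.index)
    assert set(atlas.celltype_rna.values.index) == genes
    assert set(atlas.region_proteome.values.index) == genes
    for s in atlas.truth.planted_markers.values():
        assert s <= genes
    for s in atlas.truth.planted_ligands.values():
        assert s <= genes
    assert set(atlas.truth.planted_discordant) <= genes
    for s in atlas.truth.planted_de.values():
        assert s <= genes
    graph_nodes = set(atlas.pathway_edges.a) | set(atlas.pathway_edges.b)
    assert atlas.truth.planted_short_tfs <= graph_nodes
    assert atlas.truth.planted_short_tfs <= genes
    assert set(atlas.fasta) == genes
    # matrices never carry negative values on the linear scale
    assert np.nanmin(atlas.celltype_proteome.values.to_numpy()) >= 0


def test_marker_realized_ratio_fraction(default_atlas):
    """>= 95% of planted markers keep a realized >= 2x ratio under the noise model."""
    m = default_atlas.celltype_proteome
    means = m.group_means()
    logm = np.log(means + means[means > 0].min().min() * 1e-3)
    hits = total = 0
    for ct, genes in default_atlas.truth.planted_markers.items():
        others = [c for c in means.columns if c != ct]
        geo = np.exp(logm[others].mean(axis=1))
        ratio = (means[ct] / geo).loc[sorted(genes)]
        ratio = ratio.dropna()  # fully censored markers carry no signal at all
        hits += (ratio >= 2).sum()
        total += len(ratio)
    assert hits / total >= 0.95


def test_rna_coupling_calibration():
    """Analytic copula inversion hits the Spearman target within +-0.05."""
    assert latent_copula_rho(0.48) == pytest.approx(2 * np.sin(np.pi * 0.08), rel=1e-12)
    atlas = generate_atlas(GeneratorConfig(seed=3))
    p = atlas.celltype_proteome.values
    r = atlas.celltype_rna.values
    rhos = []
    for col in p.columns:
        ok = p[col].notna()
        rhos.append(p.loc[ok, col].rank().corr(r.loc[ok, col].rank()))
    assert abs(np.mean(rhos) - 0.48) <= 0.05


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def test_networks_planted_bias_shortens_distances():
    cfg = GeneratorConfig(seed=9, **SMALL)
    tfs = [f"T{i}" for i in range(cfg.n_tfs)]
    net = generate_networks(cfg, tfs[:2], tfs=tfs)
    spec, _ = receptor_tf_path_lengths(net["graph"], net["receptors"], tfs[:2])
    other, _ = receptor_tf_path_lengths(net["graph"], net["receptors"], tfs[2:])
    assert spec.length.median() < other.length.median()


def test_networks_connected_and_simple():
    import networkx as nx

    net = generate_networks(GeneratorConfig(seed=2, **SMALL), [])
    g = net["graph"]
    assert nx.is_connected(g)
    assert nx.number_of_selfloops(g) == 0


def test_networks_unknown_planted_tf_errors():
    with pytest.raises(ConfigError, match="not in the TF node set"):
        generate_networks(GeneratorConfig(seed=2, **SMALL), ["GHOST"])


def test_networks_null_calibration():
    """Empty planted set: rejection rate at alpha 0.05 stays within [0.01, 0.10]."""
    cfg0 = GeneratorConfig()
    rejections = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        tfs = [f"T{i:03d}" for i in range(cfg0.n_tfs)]
        net = generate_networks(cfg0, [], tfs=tfs, rng=rng)
        pick = rng.choice(len(tfs), size=cfg0.n_planted_short_tfs, replace=False)
        spec, _ = receptor_tf_path_lengths(net["graph"], net["receptors"], [tfs[i] for i in pick])
        alltab, _ = receptor_tf_path_lengths(net["graph"], net["receptors"], tfs)
        rejections.append(path_length_test(spec.length, alltab.length).p_value < 0.05)
    assert 0.01 <= np.mean(rejections) <= 0.10


# ---------------------------------------------------------------------------
# peptide surface
# ---------------------------------------------------------------------------

def _mini_abundances(fasta, samples=("s1", "s2")):
    return pd.DataFrame(
        np.full((len(fasta), len(samples)), 100.0), index=list(fasta), columns=list(samples)
    )


def test_peptides_unshared_when_fraction_zero():
    cfg = GeneratorConfig(seed=1, shared_peptide_fraction=0.0, **SMALL)
    atlas_fasta = {"P1": "AAAAAAKCCCCCCCR", "P2": "DDDDDDDKEEEEEEEK"}
    t = generate_peptides(atlas_fasta, _mini_abundances(atlas_fasta), cfg)
    assert all(len(r.proteins) == 1 for r in t.records)


def test_peptides_zero_abundance_protein_absent():
    cfg = GeneratorConfig(seed=1, **SMALL)
    fasta = {"P1": "AAAAAAKCCCCCCCR", "DECOY": "DDDDDDDKEEEEEEEK"}
    ab = _mini_abundances(fasta)
    ab.loc["DECOY"] = 0.0
    t = generate_peptides(fasta, ab, cfg)
    assert not any("DECOY" in r.proteins for r in t.records)


def test_peptides_missing_fasta_errors():
    cfg = GeneratorConfig(seed=1, **SMALL)
    with pytest.raises(ConfigError, match="missing from fasta"):
        generate_peptides({"P1": "AAAAAAK"}, _mini_abundances({"P1": "x", "P9": "y"}), cfg)


def test_peptides_give_two_unique_peptides_per_planted_protein():
    cfg = GeneratorConfig(seed=6, **SMALL)
    fasta = {"P1": "AAAAAAKCCCCCCCRDDDDDDDK"}  # 3 in-bound tryptic peptides
    t = generate_peptides(fasta, _mini_abundances(fasta), cfg)
    groups = infer_proteins_parsimony(filter_peptides(t))
    (g,) = groups
    assert len(g.unique_peptides) >= 2


def test_peptide_intensities_sum_to_planted_protein():
    cfg = GeneratorConfig(
        seed=2, noise_cv=0.05, shared_peptide_fraction=0.0,
        short_peptide_fraction=0.0, low_score_fraction=0.0, **SMALL
    )
    fasta = {"P1": "AAAAAAKCCCCCCCRDDDDDDDK"}
    ab = _mini_abundances(fasta)
    t = generate_peptides(fasta, ab, cfg)
    total = sum(r.intensities["s1"] for r in t.records)
    assert total == pytest.approx(100.0, rel=0.15)  # up to replicate-level noise
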