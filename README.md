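# cardatlas

Analysis toolkit for cell-type- and region-resolved cardiac proteomes:
label-free quantification from identified-peptide tables, expression-signature
calling, proteome–transcriptome integration, over-representation analysis,
ligand–receptor–TF–target-gene crosstalk networks with a shortest-path
statistic, and case/control differential analysis. A synthetic-data generator
with planted ground truth makes the whole pipeline testable without any
external download.

## Who this is for

Proteomics and systems-biology analysts working with label-free MS data over
multiple cell-types or anatomical regions (the defaults mirror a heart study:
cardiomyocytes CM, fibroblasts CF, endothelial cells EC, immune cells IM;
regions LA/RA/LV/RV plus pericardium CP and pericardial fat PF; dilated
cardiomyopathy DCM lesions vs adjacent unaffected myocardium AUM), who need a
reproducible, scriptable implementation of the standard rule set rather than a
point-and-click platform.

## The methods at the core

* **Quantification.** Identified peptides are filtered (length ≥ 7, ion score
  ≥ 20), assembled into protein groups by the parsimony principle (greedy
  minimum set cover with deterministic tie-breaking), and groups with fewer
  than two unique peptides are discarded. Protein abundance is iBAQ — summed
  peptide intensity divided by the count of theoretically observable tryptic
  peptides (7–30 aa, Keil rule, no missed cleavages) — normalised to the
  fraction of total, FOT = iBAQ / Σ iBAQ × 10⁵ per sample, with missing values
  imputed by the global matrix minimum.
* **Signatures.** A protein is *cell-type-enhanced* when its mean FOT in one
  cell-type is ≥ 2× the geometric mean of the other cell-types; *ubiquitous*
  across regions when its median log₁₀FOT > −2; a ligand is *enriched* in a
  cell-type when its mean there is ≥ 1.5× the average over all cell-types.
* **Integration.** Spearman correlation profiles between FOT and FPKM;
  a pooled OLS baseline of log₂FOT on log₂FPKM whose vertical deviations
  dᵢ = yᵢ − m·xᵢ rank genes into protein-overexpressed (top 5%) and
  RNA-overexpressed (bottom 5%) tails; and a 3×-ratio rule flagging cell-types
  whose protein/RNA ratio lags the gene's own four-cell-type average.
* **Crosstalk.** Ligand–receptor pairs whose ligand is enriched in a source
  cell-type and whose receptor is detected in the target cell-type are walked
  through a pathway graph to transcription factors; each receptor→TF shortest
  path must carry a hypergeometrically enriched pathway (p < 0.05). Path
  lengths to cell-type-specific TFs are compared against all detected TFs by a
  one-sided Mann–Whitney U test (exact permutation p for ≤ 12 combined
  observations, tie-corrected normal approximation otherwise).
* **Differential analysis.** Unpaired Student's t (Welch optional) per protein
  on log₂FOT, two-sided raw p < 0.05, with fold-changes and BH-adjusted
  p-values reported alongside.

## Worked example

```python
from cardatlas import (GeneratorConfig, generate_atlas, impute_missing,
                       call_enhanced_proteins, correlate_protein_rna)

atlas = generate_atlas(GeneratorConfig(seed=42))     # 2,000 genes, 4 cell-types x 3 reps
fot = impute_missing(atlas.celltype_proteome)

calls = call_enhanced_proteins(fot, fold=2.0)
hits = calls[calls.passed]
print(hits.groupby("group").size().to_string())

profile = correlate_protein_rna(fot, atlas.celltype_rna)
print(f"median Spearman rho: {profile.median_per_group:.3f}")

markers = atlas.truth.planted_markers["CM"]
recovered = set(hits.loc[hits.group == "CM", "feature"]) & markers
print(f"CM markers recovered: {len(recovered)}/{len(markers)}")
```

prints

```
group
CF    103
CM    103
EC    105
IM     99
median Spearman rho: 0.464
CM markers recovered: 97/100
```

Around 100 proteins per cell-type pass the 2× enhanced rule — the 100 planted
markers per cell-type (97 of the CM set recovered; the remainder fall below
the detection limit) plus the handful of planted cell-type-restricted ligands.
The median protein–RNA Spearman correlation of 0.46 reflects the generator's
coupling target of 0.48 for moderately coupled omics layers.

The same stages are exposed on the command line:

```bash
cardatlas simulate --out atlas/ --seed 42
cardatlas quantify --peptides atlas/peptides.tsv --fasta atlas/proteins.fasta --out fot.tsv
cardatlas signatures --matrix atlas/celltype_fot.tsv --rule enhanced --out enhanced.tsv
cardatlas run --out run/            # full pipeline with a manifest
```

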