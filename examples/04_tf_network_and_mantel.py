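"""TF-gene correlation network and gene-metabolite Mantel integration.

The generator plants a latent factor shared by a transcription factor and
its targets (known-sign correlations) and couples a block of genes with a
block of metabolites.  The network stage then ranks the top-k genes per TF
by |Pearson r|, and the Mantel stage tests whether per-enzyme gene blocks
co-vary with the metabolite profiles across samples.
"""
import pandas as pd

from fluoromics import (
    PlantedOmicsDesign,
    gen_omics_dataset,
    mantel_by_group,
    tf_correlation_network,
)

design = PlantedOmicsDesign(
    tf_target_map={"gene_0010": [("gene_0011", 1.0), ("gene_0012", -1.0)]},
    coupled_genes=("gene_0020", "gene_0021"),
    coupled_metabolites=("met_0005", "met_0006"),
    gene_metabolite_coupling=1.5,
    sigma=0.1,
    seed=8,
)
tables = gen_omics_dataset(design)
tx = tables["transcript"].values

edges = tf_correlation_network(tx.loc[["gene_0010"]], tx.drop(index=["gene_0010"]), k=5)
print("top-5 genes correlated with the TF (planted targets rank first):")
print(edges.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

groups = pd.Series({
    "gene_0020": "EC:4.1.1.39", "gene_0021": "EC:4.1.1.39",   # coupled block
    "gene_0040": "EC:5.3.1.6", "gene_0041": "EC:5.3.1.6",     # background block
})
mantel = mantel_by_group(
    tx, groups, tables["metabolite"].values.loc[["met_0005", "met_0006"]],
    permutations=999, seed=0,
)
print("\nMantel test per enzyme gene-block vs the coupled metabolites:")
print(mantel.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("the coupled block shows a large Mantel r with small p; the "
      "background block does not")
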