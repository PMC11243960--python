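"""The screening and correlation rules applied to published summary tables.

Loads the packaged worked-example tables from a UV-B study of
*Rhododendron chrysanthum* and reproduces the headline counts: the
Calvin-cycle DEG calls, the GLK (G2-like) family members significant in
both UV-B comparisons, and the strong-correlation filter on the TF-gene
Pearson table.
"""
import numpy as np
import pandas as pd

from fluoromics import datasets, screen_differential

# Calvin-cycle DEGs, A (control) vs B (UV-B)
degs = datasets.load_calvin_cycle_degs().set_index("gene_id")
rec = pd.DataFrame({"fc": np.exp2(degs["log2fc_BvsA"]), "qvalue": degs["qvalue_AvsB"]})
calls = screen_differential(rec, "transcript")["call"]
print(f"Calvin-cycle DEGs: {(calls == 'up').sum()} up, {(calls == 'down').sum()} down, "
      f"{degs['ec_number'].nunique()} distinct enzymes")

# G2-like TF members significant in both UV-B comparisons
long = datasets.load_g2like_tf_members(long=True)
called = {}
for comparison, sub in long.groupby("comparison"):
    out = screen_differential(sub.set_index("gene_id")[["fc", "qvalue"]], "transcript")
    called[comparison] = set(out.index[out["call"] != "ns"])
both = sorted(called["AvsB"] & called["DvsC"])
print(f"G2-like members significant in both AvsB and DvsC: {len(both)}")
for gene in both:
    print(f"  {gene}")

# strong-correlation filter on the TF vs Calvin-cycle-gene table
pcc = datasets.load_tf_calvin_correlations()
print(f"TF-gene pairs: {len(pcc)}, min |PCC| = {pcc['pcc'].abs().min():.3f} "
      f"-> all pass the |r| > 0.9 'strongly correlated' filter: "
      f"{bool(pcc['pcc'].abs().min() > 0.9)}")
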