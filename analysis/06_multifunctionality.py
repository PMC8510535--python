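"""Ecosystem multifunctionality: per-sample index, treatment effects, drivers.

Z-scores the 18 functions, averages them into the EMF index, reports each
treatment's fold change and difference versus the control, and the
Spearman associations between EMF and the edaphic gradient.
"""

from _common import load_dataset, save

from ecoassembly.commstats import spearman_heatmap
from ecoassembly.multifunctionality import emf, emf_fold_change, zscore_functions

ENV_VARS = ["pH", "SOM", "DOC", "WS_Cd", "Ex_Cd"]


def main() -> None:
    ds = load_dataset("selection")
    meta = ds["metadata"]
    z = zscore_functions(ds["functions"])
    emf_values = emf(z)
    save(emf_values.to_frame(), "emf_per_sample.tsv")

    fold = emf_fold_change(emf_values, meta, "control")
    save(fold, "emf_treatment_effects.tsv")
    print("treatment effects on EMF (difference vs control, in z-score units):")
    print(fold[["mean_emf", "difference", "fold_change"]].round(3))

    rho, p = spearman_heatmap(emf_values.to_frame(), meta[ENV_VARS])
    corr = rho.loc["EMF"].to_frame("rho").join(p.loc["EMF"].to_frame("p"))
    save(corr, "emf_env_spearman.tsv")
    print("\nEMF vs edaphic variables (Spearman):")
    print(corr.round(4))


if __name__ == "__main__":
    main()
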