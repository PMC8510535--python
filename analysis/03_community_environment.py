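"""Community dissimilarity versus treatments, environment, and EMF.

For the rare and abundant groups separately: similarity of each treatment
to the control (1 - Bray-Curtis), the Mantel correlation between community
dissimilarity and multifunctionality distance, and a Monte Carlo
permutation test of each edaphic variable against the community ordination.
"""

import pandas as pd
from _common import N_PERM, SEED, load_dataset, save

from ecoassembly.classify import classify_taxa, group_rare_abundant
from ecoassembly.commstats import (
    bray_curtis,
    envfit_permutation,
    euclidean_distance,
    mantel,
    similarity_to_control,
)
from ecoassembly.io import relative_abundance
from ecoassembly.multifunctionality import emf, zscore_functions

ENV_VARS = ["pH", "SOM", "DOC", "WS_Cd", "Ex_Cd"]


def main() -> None:
    ds = load_dataset("selection")
    table = ds["table"].drop_empty_taxa()
    meta = ds["metadata"]
    groups = group_rare_abundant(classify_taxa(relative_abundance(table)))
    emf_values = emf(zscore_functions(ds["functions"]))
    emf_dist = euclidean_distance(emf_values)

    for group in ("rare", "abundant"):
        sub = table.subset_taxa(groups[group])
        bc = bray_curtis(sub)
        sim = similarity_to_control(bc, meta, "control")
        save(sim, f"similarity_to_control_{group}.tsv")

        m = mantel(bc, emf_dist, n_perm=N_PERM, seed=SEED)
        rows = [{"variable": "EMF_distance (Mantel r)", "statistic": m.statistic,
                 "p": m.p_value}]
        for var in ENV_VARS:
            r = envfit_permutation(bc, meta[var].to_numpy(), n_perm=N_PERM, seed=SEED)
            rows.append({"variable": f"{var} (R2)", "statistic": r.statistic,
                         "p": r.p_value})
        tests = pd.DataFrame(rows).set_index("variable")
        save(tests, f"environment_tests_{group}.tsv")
        print(f"\n=== {group} community ===")
        print(tests.round(4))
        print(f"least similar to control: {sim['mean_similarity'].idxmin()}"
              f" ({sim['mean_similarity'].min():.3f})")


if __name__ == "__main__":
    main()
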