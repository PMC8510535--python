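"""Environmental change points and group-level niche breadth.

Estimates an indicator-value change point along the gradient for every
sufficiently occupied taxon and compares the environmental breadth
(normalised IQR of change points) of the rare versus abundant groups.
"""

import pandas as pd
from _common import SEED, load_dataset, save

from ecoassembly.classify import classify_taxa, group_rare_abundant
from ecoassembly.io import relative_abundance
from ecoassembly.niche import environmental_breadth, indval_changepoint

VARIABLE = "pH"


def main() -> None:
    ds = load_dataset("selection")
    table = ds["table"].drop_empty_taxa()
    meta = ds["metadata"]
    rel = relative_abundance(table)
    groups = group_rare_abundant(classify_taxa(rel))
    env = meta[VARIABLE].to_numpy()

    rows, breadths = [], {}
    for group in ("rare", "abundant"):
        pts = []
        for taxon in groups[group]:
            abund = rel[taxon].to_numpy()
            if (abund > 0).sum() < 3:
                continue
            cp = indval_changepoint(
                abund, env, n_boot=100, seed=SEED, taxon_id=taxon, variable=VARIABLE
            )
            rows.append(
                {
                    "taxon_id": taxon, "group": group,
                    "change_point": cp.change_point, "direction": cp.direction,
                    "lo": cp.interval[0], "hi": cp.interval[1],
                    "uninformative": cp.uninformative,
                }
            )
            if not cp.uninformative:
                pts.append(cp.change_point)
        if len(pts) >= 5:
            breadths[group] = environmental_breadth(pts, (env.min(), env.max()))

    cps = pd.DataFrame(rows).set_index("taxon_id")
    save(cps, "change_points.tsv")
    breadth = pd.Series(breadths, name="breadth").rename_axis("group")
    save(breadth.to_frame(), "environmental_breadth.tsv")
    print(f"change points along {VARIABLE}: {len(cps)} taxa")
    print("\nenvironmental breadth (normalised IQR of change points):")
    print(breadth.round(3))


if __name__ == "__main__":
    main()
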