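"""Generate the three study-shaped synthetic metacommunities.

Each dataset is 33 samples (11 treatments x 3 replicates along an
environmental gradient), 300 taxa with a birth-death phylogeny and
Brownian traits, depth 5000, plus 18 gradient-responsive ecosystem
functions - one dataset per assembly regime (selection, well-mixed,
dispersal-limited).  Later drivers read these from results/datasets/.
"""

from _common import DATA_DIR, SEED

from ecoassembly.synth import SCENARIOS, ScenarioConfig, simulate_dataset, write_dataset


def main() -> None:
    for i, scenario in enumerate(SCENARIOS):
        cfg = ScenarioConfig(scenario=scenario, seed=SEED + i)
        ds = simulate_dataset(cfg, emf_effect=1.0, noise_sd=0.5)
        paths = write_dataset(ds, DATA_DIR / scenario)
        table = ds["table"]
        print(
            f"{scenario}: {len(table.sample_ids)} samples x "
            f"{len(table.taxon_ids)} taxa -> {paths['otu'].parent}"
        )


if __name__ == "__main__":
    main()
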