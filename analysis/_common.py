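"""Shared paths and loaders for the numbered analysis drivers.

Run the drivers from the repository root in order; 01 writes the synthetic
datasets that the later steps read.
"""

from pathlib import Path

from ecoassembly.io import read_functions, read_metadata, read_otu_table, read_tree

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "datasets"
OUT_DIR = ROOT / "results" / "analysis"

SEED = 17
N_NULL = 199
N_PERM = 999


def load_dataset(scenario: str = "selection"):
    d = DATA_DIR / scenario
    if not d.exists():
        raise SystemExit(
            f"dataset {d} not found - run analysis/01_simulate_metacommunities.py first"
        )
    return {
        "table": read_otu_table(d / "otu_table.tsv"),
        "tree": read_tree(d / "tree.nwk"),
        "metadata": read_metadata(d / "metadata.tsv"),
        "functions": read_functions(d / "functions.tsv"),
    }


def save(df, name: str) -> Path:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    path = OUT_DIR / name
    df.to_csv(path, sep="\t", float_format="%.6g")
    return path
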