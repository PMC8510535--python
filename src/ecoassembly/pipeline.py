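"""One-config orchestration of the full study-shaped analysis.

``run_all`` chains ingest -> rare/abundant classification -> community
statistics -> betaNTI/RC null models -> process partition -> network ->
multifunctionality -> niche breadth, writing one TSV per stage plus a
manifest (parameters, seeds, SHA-256 of every output) into the run
directory.  Every stochastic stage is seeded from the config, so an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import partition_processes, raup_crick_bray
from .classify import classify_taxa, group_rare_abundant
from .commstats import (
    bray_curtis,
    envfit_permutation,
    euclidean_distance,
    mantel,
    shannon,
    similarity_to_control,
    spearman_heatmap,
)
from .io import (
    OtuTable,
    rarefy,
    read_functions,
    read_metadata,
    read_otu_table,
    read_tree,
    relative_abundance,
)
from .multifunctionality import emf, emf_fold_change, zscore_functions
from .network import build_network, detect_modules, node_table
from .niche import environmental_breadth, indval_changepoint
from .phylo import beta_nti, ses_mntd

__all__ = ["RunConfig", "run_all"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Flat run configuration; thresholds default to the study's values."""

    otu_path: str
    tree_path: str
    metadata_path: str
    functions_path: str
    out_dir: str
    control_label: str = "control"
    orientation: str = "samples_as_rows"
    depth: int | None = None  # None = minimum sample total
    seed: int = 17
    n_null: int = 999
    n_perm: int = 999
    n_boot: int = 100
    upper_threshold: float = 0.01
    lower_threshold: float = 0.0001
    rare_group: str = "art_crt"
    bnti_bound: float = 2.0
    rc_bound: float = 0.95
    min_prevalence: float = 0.5
    min_abs_r: float = 0.8
    max_p: float = 0.05
    zi_bound: float = 2.5
    pi_bound: float = 0.62
    env_vars: list[str] = field(default_factory=list)
    niche_max_taxa: int = 200

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _log(stage: str, t0: float) -> None:
    print(f"[ecoassembly] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def run_all(config: RunConfig | str | Path) -> Path:
    """Run every stage; returns the run directory."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_toml(config)
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # ---- ingest & pre-flight ------------------------------------------
    t0 = time.perf_counter()
    table = read_otu_table(cfg.otu_path, orientation=cfg.orientation)
    tree = read_tree(cfg.tree_path)
    meta = read_metadata(cfg.metadata_path)
    functions = read_functions(cfg.functions_path)
    missing_meta = set(table.sample_ids) - set(meta.index)
    if missing_meta:
        raise ValueError(f"[ingest] metadata missing samples: {sorted(missing_meta)}")
    missing_fn = set(table.sample_ids) - set(functions.index)
    if missing_fn:
        raise ValueError(f"[ingest] functions missing samples: {sorted(missing_fn)}")
    missing_tips = set(table.taxon_ids) - set(tree.tip_labels)
    if missing_tips:
        raise ValueError(
            f"[ingest] tree tips incomplete: {sorted(missing_tips)[:5]}"
        )
    meta = meta.loc[table.sample_ids]
    functions = functions.loc[table.sample_ids]
    table = rarefy(table, depth=cfg.depth, seed=cfg.seed).drop_empty_taxa()
    env_vars = cfg.env_vars or [
        c
        for c in meta.columns
        if c not in ("treatment", "replicate")
        and np.issubdtype(meta[c].dtype, np.number)
    ]
    table.to_tsv(out / "rarefied_otu_table.tsv")
    outputs["rarefied_otu_table"] = out / "rarefied_otu_table.tsv"
    _log("ingest", t0)

    # ---- classification ------------------------------------------------
    t0 = time.perf_counter()
    rel = relative_abundance(table)
    cls = classify_taxa(rel, upper=cfg.upper_threshold, lower=cfg.lower_threshold)
    _write(cls, out / "classification.tsv")
    outputs["classification"] = out / "classification.tsv"
    groups = group_rare_abundant(cls, rare_group=cfg.rare_group)
    _log("classify", t0)

    # ---- multifunctionality (needed by community stats) ----------------
    t0 = time.perf_counter()
    z = zscore_functions(functions)
    emf_values = emf(z)
    emf_df = emf_values.to_frame()
    _write(emf_df, out / "emf_per_sample.tsv")
    outputs["emf_per_sample"] = out / "emf_per_sample.tsv"
    fold = emf_fold_change(emf_values, meta, cfg.control_label)
    _write(fold, out / "emf_fold_change.tsv")
    outputs["emf_fold_change"] = out / "emf_fold_change.tsv"
    rho, pv = spearman_heatmap(emf_df, meta[env_vars])
    corr = pd.DataFrame({"rho": rho.loc["EMF"], "p": pv.loc["EMF"]})
    _write(corr, out / "emf_env_spearman.tsv")
    outputs["emf_env_spearman"] = out / "emf_env_spearman.tsv"
    emf_dist = euclidean_distance(emf_values)
    _log("multifunctionality", t0)

    # ---- per-group statistics, null models, partition, niche -----------
    for group in ("rare", "abundant"):
        taxa = groups[group]
        if len(taxa) < 2:
            print(
                f"[ecoassembly] skipping group {group}: fewer than 2 taxa",
                file=sys.stderr,
            )
            continue
        t0 = time.perf_counter()
        sub = table.subset_taxa(taxa)
        nonzero = sub.sample_totals > 0
        if not nonzero.all():
            raise ValueError(
                f"[stats:{group}] samples without {group} taxa: "
                f"{list(nonzero.index[~nonzero])}"
            )
        bc = bray_curtis(sub)
        alpha = pd.DataFrame(
            {"shannon": [shannon(row) for row in sub.matrix]}, index=sub.sample_ids
        )
        _write(alpha, out / f"alpha_{group}.tsv")
        outputs[f"alpha_{group}"] = out / f"alpha_{group}.tsv"
        sim = similarity_to_control(bc, meta, cfg.control_label)
        _write(sim, out / f"similarity_{group}.tsv")
        outputs[f"similarity_{group}"] = out / f"similarity_{group}.tsv"

        m = mantel(bc, emf_dist, n_perm=cfg.n_perm, seed=cfg.seed)
        envfit_rows = [
            {"variable": "EMF_distance_mantel", "statistic": m.statistic, "p": m.p_value}
        ]
        for var in env_vars:
            r = envfit_permutation(
                bc, meta[var].to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed
            )
            envfit_rows.append(
                {"variable": var, "statistic": r.statistic, "p": r.p_value}
            )
        _write(
            pd.DataFrame(envfit_rows).set_index("variable"),
            out / f"env_tests_{group}.tsv",
        )
        outputs[f"env_tests_{group}"] = out / f"env_tests_{group}.tsv"
        _log(f"stats:{group}", t0)

        t0 = time.perf_counter()
        rich_enough = (sub.counts > 0).sum(axis=1) >= 2
        ses = ses_mntd(
            OtuTable(sub.counts.loc[rich_enough]),
            tree,
            n_null=cfg.n_null,
            seed=cfg.seed,
        )
        _write(ses, out / f"ses_mntd_{group}.tsv")
        outputs[f"ses_mntd_{group}"] = out / f"ses_mntd_{group}.tsv"
        nti = beta_nti(sub, tree, n_null=cfg.n_null, seed=cfg.seed)
        long = nti.to_long()
        rc = raup_crick_bray(sub, n_null=cfg.n_null, seed=cfg.seed)
        result = partition_processes(nti.score, rc)
        long = long.merge(
            result.pairs[["sample_i", "sample_j", "rc_bray", "process"]],
            on=["sample_i", "sample_j"],
        )
        long.to_csv(out / f"assembly_{group}.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)
        outputs[f"assembly_{group}"] = out / f"assembly_{group}.tsv"
        _write(
            result.proportions.rename_axis("process").to_frame(),
            out / f"process_proportions_{group}.tsv",
        )
        outputs[f"process_proportions_{group}"] = (
            out / f"process_proportions_{group}.tsv"
        )
        _log(f"assembly:{group}", t0)

        t0 = time.perf_counter()
        rel_sub = relative_abundance(sub)
        occupied = (rel_sub > 0).sum(axis=0)
        cp_taxa = [t for t in rel_sub.columns if occupied[t] >= 3]
        cp_taxa = cp_taxa[: cfg.niche_max_taxa]
        cp_rows = []
        for var in env_vars:
            envv = meta[var].to_numpy(dtype=float)
            for t in cp_taxa:
                try:
                    cp = indval_changepoint(
                        rel_sub[t].to_numpy(), envv, n_boot=cfg.n_boot,
                        seed=cfg.seed, taxon_id=t, variable=var,
                    )
                except ValueError:
                    continue
                cp_rows.append(
                    {
                        "taxon_id": t, "variable": var,
                        "change_point": cp.change_point,
                        "direction": cp.direction, "score": cp.score,
                        "lo": cp.interval[0], "hi": cp.interval[1],
                        "uninformative": cp.uninformative,
                    }
                )
        cp_df = pd.DataFrame(cp_rows)
        cp_df.to_csv(out / f"change_points_{group}.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
        outputs[f"change_points_{group}"] = out / f"change_points_{group}.tsv"
        breadth_rows = []
        for var in env_vars:
            pts = cp_df[
                (cp_df["variable"] == var) & (~cp_df["uninformative"])
            ]["change_point"] if len(cp_df) else []
            if len(pts) >= 5:
                rng_var = (meta[var].min(), meta[var].max())
                breadth_rows.append(
                    {
                        "variable": var,
                        "breadth": environmental_breadth(pts, rng_var),
                        "n_taxa": len(pts),
                    }
                )
        pd.DataFrame(breadth_rows).to_csv(
            out / f"environmental_breadth_{group}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        outputs[f"environmental_breadth_{group}"] = (
            out / f"environmental_breadth_{group}.tsv"
        )
        _log(f"niche:{group}", t0)

    # ---- network --------------------------------------------------------
    t0 = time.perf_counter()
    tags = cls[["group"]].copy()
    net = build_network(
        table,
        min_prevalence=cfg.min_prevalence,
        min_abs_r=cfg.min_abs_r,
        max_p=cfg.max_p,
        node_tags=tags,
    )
    edge_rows = [
        {"source": a, "target": b, "rho": d["rho"], "sign": d["sign"]}
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "rho", "sign"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    outputs["network_edges"] = out / "network_edges.tsv"
    if net.number_of_edges() > 0:
        modules, q = detect_modules(net, seed=cfg.seed)
        nodes = node_table(net, modules)
        print(f"[ecoassembly] network modularity Q = {q:.3f}", file=sys.stderr)
    else:
        nodes = pd.DataFrame(
            columns=["module", "degree", "within_degree", "Zi", "Pi", "role"]
        )
        nodes.index.name = "taxon_id"
    _write(nodes, out / "network_nodes.tsv")
    outputs["network_nodes"] = out / "network_nodes.tsv"
    _log("network", t0)

    # ---- manifest -------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
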