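"""End-to-end orchestration: synth (or real tables) -> community -> network
-> association -> lefse, driven by one YAML config, with a run manifest.

The manifest records the config hash, input-table hashes, package version,
per-stage row counts and a SHA-256 per output file, so two runs with the
same config and seed can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import community as comm
from . import lefse as lefse_mod
from . import network as net
from . import synth as synth_mod
from . import tables_io as io
from .tables_io import ValidationError

log = logging.getLogger(__name__)

#: Every threshold the pipeline applies lives here, once.
DEFAULT_CONFIG: dict = {
    "seed": None,                   # mandatory, no default
    "output_dir": "rhizonet_out",
    "synth": {},                    # SyntheticSpec overrides; ignored if inputs set
    "inputs": None,                 # {counts, design, physiology, metabolites}
    "network": {"min_abs_r": 0.6, "max_p": 0.05, "prevalence": 0.8,
                "scope": "per-treatment", "core_quantile": 0.9,
                "correlation_p": "t"},
    "community": {"alpha": 0.05, "top_n": 20, "flag_on": "p"},
    "association": {"n_perm": 999, "metric": "euclidean",
                    "method": "spearman"},
    "lefse": {"alpha": 0.05, "lda_threshold": 3.5, "n_boot": 30,
              "boot_fraction": 2 / 3},
}


@dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        merged = _deep_merge(DEFAULT_CONFIG, d or {})
        cfg = cls(merged)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=True))

    def validate(self) -> None:
        if self.raw.get("seed") is None:
            raise ValidationError("config must set an explicit integer 'seed'")
        if not isinstance(self.raw["seed"], int):
            raise ValidationError("'seed' must be an integer")
        netc = self.raw["network"]
        net.EdgeRule(min_abs_r=netc["min_abs_r"], max_p=netc["max_p"],
                     prevalence=netc["prevalence"], scope=netc["scope"])
        if not 0 <= netc["core_quantile"] <= 1:
            raise ValidationError("core_quantile must be in [0,1]")
        for key in ("alpha",):
            if not 0 < self.raw["community"][key] < 1:
                raise ValidationError("community alpha must be in (0,1)")
        if self.raw["association"]["n_perm"] < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.raw["lefse"]["lda_threshold"] <= 0:
            raise ValidationError("lda_threshold must be positive")

    def __getitem__(self, key):
        return self.raw[key]


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _deep_merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = json.loads(json.dumps(v)) if isinstance(v, dict) else v
    for k, v in override.items():
        if k not in out:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, label: str,
               manifest: dict) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
    manifest["outputs"][path.name] = _sha256(path)
    manifest["row_counts"][f"{label}:{path.name}"] = int(len(df))


def run_all(config: RunConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    t0 = time.time()
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    manifest: dict = {"version": __version__, "seed": seed,
                      "config_sha256": hashlib.sha256(
                          json.dumps(config.raw, sort_keys=True,
                                     default=str).encode()).hexdigest(),
                      "inputs": {}, "outputs": {}, "row_counts": {},
                      "warnings": [], "stages": {}}

    # -- stage: inputs / synth ------------------------------------------------
    t_stage = time.time()
    if config["inputs"]:
        paths = config["inputs"]
        counts = io.read_count_table(paths["counts"])
        design = io.read_design(paths["design"])
        physiology = io.read_traits(paths["physiology"])
        metabolites = io.read_traits(paths["metabolites"])
        truth = None
        for k, p in paths.items():
            manifest["inputs"][k] = _sha256(Path(p))
    else:
        spec = synth_mod.SyntheticSpec(**{**config["synth"], "seed": seed})
        study = synth_mod.generate_study(spec)
        counts, design = study.counts, study.design
        physiology, metabolites = study.physiology, study.metabolites
        truth = study.truth
        written = synth_mod.write_study(study, outdir / "synth")
        for k, p in written.items():
            manifest["outputs"][f"synth/{Path(p).name}"] = _sha256(Path(p))
    io.check_sample_consistency(counts, design, physiology, metabolites)
    manifest["stages"]["inputs"] = round(time.time() - t_stage, 3)

    # -- stage: community -----------------------------------------------------
    t_stage = time.time()
    ccfg = config["community"]
    props = comm.relative_abundance(counts)
    div = comm.diversity_report(counts, design)
    _write_tsv(div["per_sample"], outdir / "diversity_per_sample.tsv",
               "community", manifest)
    _write_tsv(div["pairwise"], outdir / "diversity_pairwise.tsv",
               "community", manifest)
    for rank in ("phylum", "genus"):
        comp = comm.top_n_composition(props, counts.rank_names(rank),
                                      n=ccfg["top_n"])
        _write_tsv(comp, outdir / f"composition_top{ccfg['top_n']}_{rank}.tsv",
                   "community", manifest)
    screen = comm.kruskal_genus_screen(props, design, alpha=ccfg["alpha"],
                                       flag_on=ccfg["flag_on"])
    _write_tsv(screen.table, outdir / "kruskal_genus_screen.tsv",
               "community", manifest)
    manifest["stages"]["community"] = round(time.time() - t_stage, 3)

    # -- stage: network -------------------------------------------------------
    t_stage = time.time()
    ncfg = config["network"]
    rule = net.EdgeRule(min_abs_r=ncfg["min_abs_r"], max_p=ncfg["max_p"],
                        prevalence=ncfg["prevalence"], scope=ncfg["scope"])
    genus_names = counts.rank_names("genus")
    nets = net.networks_per_scope(counts, design, rule,
                                  method=ncfg["correlation_p"],
                                  genus_names=genus_names)
    topo = net.topology_table(nets, seed=seed)
    _write_tsv(topo, outdir / "topology.tsv", "network", manifest)
    core_union: set[str] = set()
    core_frames = []
    for label, g in nets.items():
        result = net.core_taxa(g, q=ncfg["core_quantile"])
        core_union.update(result.core)
        frame = result.table.copy()
        frame.insert(0, "network", label)
        core_frames.append(frame)
        for node in g.nodes:
            g.nodes[node]["core"] = bool(result.table.loc[node, "core"])
            g.nodes[node]["closeness"] = float(result.table.loc[node, "closeness"])
            g.nodes[node]["degree"] = int(result.table.loc[node, "degree"])
        io.export_graphml(g, outdir / f"network_{label}.graphml")
        manifest["outputs"][f"network_{label}.graphml"] = _sha256(
            outdir / f"network_{label}.graphml")
        edges = pd.DataFrame(
            [(u, v, d["rho"], d["sign"], d["p"]) for u, v, d in
             g.edges(data=True)],
            columns=["source", "target", "rho", "sign", "p"])
        _write_tsv(edges.set_index("source"),
                   outdir / f"edges_{label}.tsv", "network", manifest)
    core_table = (pd.concat(core_frames) if core_frames
                  else pd.DataFrame(columns=["network"]))
    _write_tsv(core_table, outdir / "core_taxa.tsv", "network", manifest)
    manifest["stages"]["network"] = round(time.time() - t_stage, 3)

    # -- stage: lefse ---------------------------------------------------------
    t_stage = time.time()
    lcfg = config["lefse"]
    lefse_res = lefse_mod.lefse_screen(
        metabolites, design, alpha=lcfg["alpha"],
        lda_threshold=lcfg["lda_threshold"], n_boot=lcfg["n_boot"],
        boot_fraction=lcfg["boot_fraction"], seed=seed)
    _write_tsv(lefse_res.table, outdir / "lefse_metabolites.tsv",
               "lefse", manifest)
    manifest["stages"]["lefse"] = round(time.time() - t_stage, 3)

    # -- stage: association ---------------------------------------------------
    t_stage = time.time()
    acfg = config["association"]
    enriched = screen.table.index[screen.table["significant"]].tolist()
    dominant = props.mean(axis=1).sort_values(ascending=False).index[:10].tolist()
    groups = {
        "dominant_taxa": assoc.group_abundance(props, dominant),
        "alpha_diversity": div["per_sample"]["shannon"],
    }
    if enriched:
        groups["enriched_taxa"] = assoc.group_abundance(props, enriched)
    if core_union:
        groups["core_taxa"] = assoc.group_abundance(
            props, sorted(core_union & set(props.index)))
    phys_dist = assoc.distance_matrix(physiology.table, metric=acfg["metric"])
    mantel_rows = []
    for k, (name, vec) in enumerate(sorted(groups.items())):
        gdist = assoc.distance_matrix(vec.loc[physiology.samples].to_frame(),
                                      metric=acfg["metric"])
        res = assoc.mantel(gdist.to_numpy(), phys_dist.to_numpy(),
                           method=acfg["method"], n_perm=acfg["n_perm"],
                           seed=seed + 1000 + k,
                           labels=(name, "physiology"))
        mantel_rows.append((name, res.r, res.p, res.n_permutations))
    mantel_df = pd.DataFrame(mantel_rows,
                             columns=["group", "r", "p", "n_perm"]
                             ).set_index("group")
    _write_tsv(mantel_df, outdir / "mantel_physiology.tsv", "association",
               manifest)

    feature_cols = {}
    for g in sorted(set(enriched) | core_union):
        if g in props.index:
            feature_cols[g] = props.loc[g]
    features = (pd.DataFrame(feature_cols) if feature_cols
                else props.T.iloc[:, :10])
    heat_phys = assoc.group_trait_heatmap(features, physiology.table,
                                          method=acfg["method"])
    for part in ("rho", "p", "q", "stars"):
        _write_tsv(getattr(heat_phys, part),
                   outdir / f"heatmap_physiology_{part}.tsv", "association",
                   manifest)
    diff_feats = lefse_res.passing
    met_cols = diff_feats if diff_feats else list(
        lefse_res.table.index[:min(14, len(lefse_res.table))])
    heat_met = assoc.group_trait_heatmap(features,
                                         metabolites.table[met_cols],
                                         method=acfg["method"])
    for part in ("rho", "p", "q", "stars"):
        _write_tsv(getattr(heat_met, part),
                   outdir / f"heatmap_metabolites_{part}.tsv", "association",
                   manifest)
    manifest["stages"]["association"] = round(time.time() - t_stage, 3)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
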