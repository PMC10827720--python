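"""Pipeline orchestration behind a single validated configuration mapping.

Stages: load-or-simulate, regulon inference per regulator, activity
inference, MAA table with cut-point search (or a fixed threshold),
survival analyses (dichotomized, five-stratum, multivariate, per-stage),
and binary-feature screens.  Every stage reads/writes only the documented
TSV/JSON formats, so stages stay independently testable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, activity, assoc, cohort, expression_io, maa
from . import regulon as regmod
from . import survival as surv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and cause."""


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths to expression/isoform-map/clinical and
    optional features TSVs) or ``simulate`` (SimParams fields) must be set.
    """

    raw: dict
    seed: int = 0
    inputs: dict | None = None
    simulate: dict | None = None
    tfs: dict = field(default_factory=dict)
    regulon: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)
    maa: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    screens: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, cfg: dict) -> "PipelineConfig":
        if not isinstance(cfg, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(cfg) - {
            "seed", "inputs", "simulate", "tfs", "regulon", "activity",
            "maa", "survival", "screens", "log_level",
        }
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        has_inputs = bool(cfg.get("inputs"))
        has_sim = "simulate" in cfg and cfg["simulate"] is not None
        if has_inputs == has_sim:
            raise ConfigError("config needs exactly one of 'inputs' or 'simulate'")
        tfs = cfg.get("tfs", {})
        if has_inputs:
            if not tfs:
                raise ConfigError("'tfs' (regulator definitions) required with inputs")
            for name, spec in tfs.items():
                if "gene" not in spec or not spec.get("isoforms"):
                    raise ConfigError(f"tf {name!r} needs 'gene' and 'isoforms'")
        return cls(
            raw=cfg,
            seed=int(cfg.get("seed", 0)),
            inputs=cfg.get("inputs"),
            simulate=cfg.get("simulate") if has_sim else None,
            tfs=tfs,
            regulon=cfg.get("regulon", {}),
            activity=cfg.get("activity", {}),
            maa=cfg.get("maa", {}),
            survival=cfg.get("survival", {}),
            screens=cfg.get("screens", {}),
            log_level=str(cfg.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("data")
def load_or_simulate(config: PipelineConfig, out: Path):
    if config.simulate is not None:
        params = cohort.SimParams(**{**config.simulate, "seed": config.seed})
        syn = cohort.generate_cohort(params)
        data_dir = out / "data"
        cohort.write_cohort(syn, data_dir, force=True)
        tfs = {
            tf: {"gene": tf, "isoforms": list(isos)}
            for tf, isos in syn.isoform_map.tf_isoforms.items()
        }
        return syn.expression, syn.isoform_map, syn.clinical, syn.features, tfs
    inp = config.inputs
    expr = expression_io.read_expression_matrix(
        inp["expression"], feature_level=inp.get("feature_level", "isoform")
    )
    if "isoform_map" in inp:
        imap = expression_io.read_isoform_map(inp["isoform_map"])
    else:
        imap = expression_io.IsoformMap({f: f for f in expr.feature_ids})
    clin = expression_io.read_clinical(inp["clinical"])
    feats = None
    if inp.get("features"):
        feats = pd.read_csv(inp["features"], sep="\t")
        feats["sample_id"] = feats["sample_id"].astype(str)
    return expr, imap, clin, feats, config.tfs


@_stage("regulon")
def run_regulons(config, expr, imap, tfs, out: Path):
    gene_mat = (
        expression_io.aggregate_to_gene(expr, imap, rule="sum")
        if expr.feature_level == "isoform"
        else expr
    )
    reg_cfg = regmod.RegulonConfig(
        alpha=float(config.regulon.get("alpha", 1e-130)),
        n_perm=int(config.regulon.get("n_perm", 1000)),
        min_regulon_size=int(config.regulon.get("min_size", 10)),
        seed=config.seed,
        top_k=config.regulon.get("top_k"),
    )
    tf_genes = {spec["gene"] for spec in tfs.values()}
    all_isoforms = {iso for spec in tfs.values() for iso in spec["isoforms"]}
    regulons = []
    for tf, spec in tfs.items():
        reg = regmod.infer_regulon(
            expr if expr.feature_level == "isoform" else gene_mat,
            gene_mat,
            tf_id=spec["gene"],
            isoform_ids=spec["isoforms"],
            config=reg_cfg,
            exclude=tf_genes | all_isoforms,
        )
        regmod.write_regulon_tsv(reg, out / f"regulon_{tf}.tsv")
        regulons.append(reg)
    return gene_mat, regulons


@_stage("activity")
def run_activity(config, gene_mat, regulons, out: Path):
    prof = activity.activity_matrix(
        gene_mat, regulons, min_overlap=int(config.activity.get("min_overlap", 10))
    )
    activity.write_activity_tsv(prof, out / "activity.tsv")
    return prof


@_stage("maa")
def run_maa(config, expr, tfs, prof, clin, out: Path, threshold_override=None):
    (tf1, spec1), (tf2, spec2) = list(tfs.items())[:2]
    a1 = prof.activity(spec1["gene"]).to_numpy()
    a2 = prof.activity(spec2["gene"]).to_numpy()
    sample_ids = list(prof.data.index)
    # regulator expression = sum of its designated isoform rows
    e1 = sum(expr.row(i) for i in spec1["isoforms"])
    e2 = sum(expr.row(i) for i in spec2["isoforms"])

    threshold = threshold_override
    if threshold is None:
        threshold = config.maa.get("threshold")
    cut_res = None
    if threshold is None:
        merged = pd.DataFrame({"sample_id": sample_ids, "maa": [
            maa.compute_maa(x, y) for x, y in zip(a1, a2)
        ]}).merge(clin.data, on="sample_id")
        ok = merged["os_time"].notna() & merged["os_event"].notna()
        cut_res = surv.optimal_cutpoint(
            merged.loc[ok, "maa"],
            merged.loc[ok, "os_time"],
            merged.loc[ok, "os_event"],
            q_low=float(config.survival.get("q_low", 0.10)),
            q_high=float(config.survival.get("q_high", 0.90)),
            mode=config.survival.get("cutpoint_mode", "logrank"),
        )
        threshold = cut_res.threshold
    table = maa.build_maa_table(sample_ids, a1, a2, e1, e2, threshold=threshold)
    maa.write_maa_tsv(table, out / "maa.tsv")
    return table, cut_res


@_stage("survival")
def run_survival(config, table, clin, out: Path, cut_res):
    merged = table.data.merge(clin.data, on="sample_id")
    results = {"threshold": float(table.threshold), "tie_rule": table.tie_rule}
    if cut_res is not None:
        results["cutpoint"] = cut_res.to_dict()
    endpoints = config.survival.get("endpoints", ["os"])
    for ep in endpoints:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol not in merged.columns:
            continue
        ok = merged[tcol].notna() & merged[ecol].notna() & (merged[tcol] > 0)
        sub = merged[ok]
        ep_res = {}
        lr = surv.logrank_test(sub[tcol], sub[ecol], sub["group"])
        ep_res["dichotomized_logrank"] = {
            "chi2": lr.statistic, "df": lr.df, "p": lr.p_value,
            "n_below": int((sub["group"] == "below").sum()),
            "n_above": int((sub["group"] == "above").sum()),
        }
        for grp in ("below", "above"):
            g = sub[sub["group"] == grp]
            surv.km_curve(g[tcol], g[ecol]).to_frame().to_csv(
                out / f"km_{ep}_{grp}.tsv", sep="\t", index=False
            )
        strata_present = sub["stratum"].unique()
        if len(strata_present) >= 2:
            lr5 = surv.logrank_test(sub[tcol], sub[ecol], sub["stratum"])
            ep_res["stratum_logrank"] = {
                "chi2": lr5.statistic, "df": lr5.df, "p": lr5.p_value,
                "n_strata": int(len(strata_present)),
            }
        ep_res["stage_analysis"] = surv.stage_stratified_analysis(
            sub["maa"].to_numpy(), sub, endpoint=ep
        )
        results[ep] = ep_res
    with open(out / "survival.json", "w") as fh:
        json.dump(results, fh, indent=1, default=float)
    return results


@_stage("screens")
def run_screens(config, table, feats, out: Path):
    if feats is None:
        return None
    merged = table.data[["sample_id", "group"]].merge(feats, on="sample_id")
    fcols = [c for c in feats.columns if c != "sample_id"]
    res = assoc.group_feature_screen(
        merged[fcols],
        merged["group"].to_numpy(),
        test=config.screens.get("test", "fisher"),
        correction=config.screens.get("correction", "bonferroni"),
    )
    df = assoc.screen_to_frame(res)
    df.to_csv(out / "screen_features.tsv", sep="\t", index=False)
    return df


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
    threshold: float | None = None,
) -> dict:
    """Run every stage; returns a manifest of produced artifacts."""
    if seed is not None:
        config.seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    expr, imap, clin, feats, tfs = load_or_simulate(config, out)
    gene_mat, regulons = run_regulons(config, expr, imap, tfs, out)
    prof = run_activity(config, gene_mat, regulons, out)
    table, cut_res = run_maa(config, expr, tfs, prof, clin, out, threshold)
    results = run_survival(config, table, clin, out, cut_res)
    run_screens(config, table, feats, out)

    import pandas, scipy  # noqa: PLC0415

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "threshold": float(table.threshold),
        "versions": {
            "mrbalance": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"manifest": manifest, "survival": results}
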