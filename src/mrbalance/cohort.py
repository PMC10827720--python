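"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two anti-correlated regulator programs drive disjoint signed-target gene
sets; per-sample survival depends on the true balance index through a
planted per-unit hazard ratio; binary features have group-dependent rates.
All randomness flows from one integer seed through named substreams, and
the ground truth is quarantined in its own structure/file so analysis-facing
tables never contain it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import (
    ClinicalTable,
    ExpressionMatrix,
    IsoformMap,
    write_clinical,
    write_expression_matrix,
)

logger = logging.getLogger(__name__)

TF1 = "TF1"  # TTF1-like regulator
TF2 = "TF2"  # p40-like regulator

_SUBSTREAMS = ("latent", "regulon", "noise", "survival", "censoring", "features",
               "clinical")


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Generator knobs.

    Regulon sizes default to the sizes of the two published networks
    (111 and 135 targets).  ``maa_hr`` is the planted per-unit hazard
    ratio of the true balance index; ``stage_hr`` an optional per-step
    stage effect.  ``feature_rates`` maps feature name -> (rate in the
    low-index group, rate in the high-index group); defaults mirror the
    reported TP53 / RASA1 / KRAS mutation frequencies.
    """

    n_samples: int = 400
    n_genes: int = 1000
    k1: int = 111
    k2: int = 135
    polarized_fraction: float = 0.8
    activity_scale: float = 5.0
    activity_jitter_sd: float = 0.1
    target_noise_sd: float = 0.25
    mode_positive_fraction: float = 0.7
    weight_range: tuple[float, float] = (0.5, 1.0)
    tf_baseline_log2: float = 6.0
    maa_hr: float = 0.74
    stage_hr: float = 1.0
    baseline_hazard: float = 1.0 / 1500.0
    censoring_fraction: float = 0.30
    rfs_hazard_multiplier: float = 1.4
    feature_threshold: float = 2.92
    feature_rates: dict = field(
        default_factory=lambda: {
            "TP53": (0.759, 0.596),
            "RASA1": (0.076, 0.012),
            "KRAS": (0.092, 0.207),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.polarized_fraction <= 1:
            raise CohortError("polarized_fraction must be in [0, 1]")
        if self.target_noise_sd < 0 or self.activity_jitter_sd < 0:
            raise CohortError("noise sds must be >= 0")
        if self.maa_hr <= 0 or self.stage_hr <= 0:
            raise CohortError("hazard ratios must be > 0")
        if self.k1 + self.k2 + 2 > self.n_genes:
            raise CohortError("k1 + k2 + 2 must not exceed n_genes")
        if not 0 <= self.censoring_fraction < 1:
            raise CohortError("censoring_fraction must be in [0, 1)")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # isoform-level, linear scale
    isoform_map: IsoformMap
    clinical: ClinicalTable
    features: pd.DataFrame  # sample_id + binary feature columns
    truth: dict  # params + latent ground truth; never written to data files


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def tune_uniform_censoring(
    times: np.ndarray, u: np.ndarray, fraction: float
) -> tuple[np.ndarray, float]:
    """Uniform(0, tau) censoring times hitting a requested realized fraction.

    ``u`` are per-subject Uniform(0,1) draws; tau is found by bisection on
    the realized censoring fraction, which is monotone in tau.  Returns
    (censoring times, tau).  fraction = 0 disables censoring.
    """
    if fraction == 0:
        return np.full(times.size, np.inf), float("inf")
    if not 0 < fraction < 1:
        raise CohortError("censoring fraction must be in [0, 1)")
    lo, hi = 1e-9, float(times.max()) * 2 + 1.0
    # realized fraction decreases as tau grows
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(mid * u < times))
        if frac > fraction:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    return tau * u, tau


def generate_cohort(params: SimParams) -> SyntheticCohort:
    """Draw a full synthetic cohort from one seed.

    Latent polarization ``d = s*b`` with sign s = +/-1 equiprobable and
    b ~ Beta(5, 1.5) for polarized samples, Beta(1.5, 5) otherwise.  True
    activities A1 = c*d + jitter, A2 = -c*d + jitter.  Regulator expression
    is 2^(A + baseline), split over two isoforms; target expression is
    2^(mu + mode*weight*A + noise); background genes are pure noise.  Event
    times are exponential with hazard ``h0 * maa_hr^MAA_true`` (times an
    optional stage effect), censored by an independent uniform tuned to the
    requested fraction.
    """
    rng = _rngs(params.seed)
    n = params.n_samples

    # --- latent polarization and true activities -------------------------
    r = rng["latent"]
    sign = np.where(r.random(n) < 0.5, -1.0, 1.0)
    polarized = r.random(n) < params.polarized_fraction
    b = np.where(polarized, r.beta(5.0, 1.5, size=n), r.beta(1.5, 5.0, size=n))
    d = sign * b
    c = params.activity_scale
    a1 = c * d + r.normal(0.0, params.activity_jitter_sd, size=n)
    a2 = -c * d + r.normal(0.0, params.activity_jitter_sd, size=n)
    maa_true = (np.abs(a1) + np.abs(a2)) / 2.0

    # --- regulon structure ------------------------------------------------
    r = rng["regulon"]
    gene_ids = [f"G{i:05d}" for i in range(params.n_genes)]
    perm = r.permutation(params.n_genes)
    targets1 = sorted(gene_ids[i] for i in perm[: params.k1])
    targets2 = sorted(gene_ids[i] for i in perm[params.k1 : params.k1 + params.k2])
    modes1 = np.where(r.random(params.k1) < params.mode_positive_fraction, 1.0, -1.0)
    modes2 = np.where(r.random(params.k2) < params.mode_positive_fraction, 1.0, -1.0)
    w_lo, w_hi = params.weight_range
    weights1 = r.uniform(w_lo, w_hi, size=params.k1)
    weights2 = r.uniform(w_lo, w_hi, size=params.k2)

    # --- expression matrix (isoform level, linear scale) ------------------
    r = rng["noise"]
    mu = {g: m for g, m in zip(gene_ids, r.uniform(4.0, 8.0, size=params.n_genes))}
    log2x = np.empty((params.n_genes, n))
    t1 = dict(zip(targets1, range(params.k1)))
    t2 = dict(zip(targets2, range(params.k2)))
    for gi, g in enumerate(gene_ids):
        noise = r.normal(0.0, params.target_noise_sd, size=n)
        if g in t1:
            j = t1[g]
            log2x[gi] = mu[g] + modes1[j] * weights1[j] * a1 + noise
        elif g in t2:
            j = t2[g]
            log2x[gi] = mu[g] + modes2[j] * weights2[j] * a2 + noise
        else:
            log2x[gi] = mu[g] + noise

    sample_ids = [f"S{i:04d}" for i in range(n)]
    iso_split = (0.6, 0.4)  # fixed isoform shares of each regulator's total
    tf_rows = {}
    for tf, act in ((TF1, a1), (TF2, a2)):
        total = np.power(2.0, act + params.tf_baseline_log2)
        for k, share in enumerate(iso_split, start=1):
            tf_rows[f"{tf}.{k}"] = total * share

    feature_ids = [f"{g}.1" for g in gene_ids] + list(tf_rows)
    values = np.vstack([np.power(2.0, log2x)] + [tf_rows[f] for f in tf_rows])
    expression = ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        log_transformed=False,
        feature_level="isoform",
    )
    mapping = {f"{g}.1": g for g in gene_ids}
    mapping.update({iso: iso.split(".")[0] for iso in tf_rows})
    isoform_map = IsoformMap(
        mapping=mapping,
        tf_isoforms={
            TF1: tuple(f"{TF1}.{k}" for k in range(1, len(iso_split) + 1)),
            TF2: tuple(f"{TF2}.{k}" for k in range(1, len(iso_split) + 1)),
        },
    )

    # --- clinical covariates ----------------------------------------------
    r = rng["clinical"]
    stages = r.choice(
        ["I", "II", "IIIA", "IIIB", "IV"], size=n, p=[0.5, 0.25, 0.15, 0.05, 0.05]
    )
    stage_step = pd.Series(stages).map(
        {"I": 0, "II": 1, "IIIA": 2, "IIIB": 2, "IV": 3}
    ).to_numpy()
    sex = np.where(r.random(n) < 0.6, "M", "F")
    age = np.clip(r.normal(67.0, 8.0, size=n), 30.0, 90.0)
    pack_years = r.gamma(2.0, 20.0, size=n)
    pack_years[r.random(n) < 0.2] = np.nan

    # --- survival ----------------------------------------------------------
    r = rng["survival"]
    hazard = (
        params.baseline_hazard
        * np.power(params.maa_hr, maa_true)
        * np.power(params.stage_hr, stage_step)
    )
    os_latent = r.exponential(1.0 / hazard)
    rfs_latent = r.exponential(1.0 / (hazard * params.rfs_hazard_multiplier))
    rc = rng["censoring"]
    cens_os, tau_os = tune_uniform_censoring(
        os_latent, rc.random(n), params.censoring_fraction
    )
    cens_rfs, tau_rfs = tune_uniform_censoring(
        rfs_latent, rc.random(n), params.censoring_fraction
    )
    os_event = (os_latent <= cens_os).astype(int)
    os_time = np.minimum(os_latent, cens_os)
    rfs_event = (rfs_latent <= cens_rfs).astype(int)
    rfs_time = np.minimum(rfs_latent, cens_rfs)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "os_time": np.round(os_time, 6),
                "os_event": os_event,
                "rfs_time": np.round(rfs_time, 6),
                "rfs_event": rfs_event,
                "stage": stages,
                "sex": sex,
                "age": np.round(age, 1),
                "pack_years": np.round(pack_years, 1),
            }
        )
    )

    # --- binary features ----------------------------------------------------
    r = rng["features"]
    low_group = maa_true < params.feature_threshold
    feat = {"sample_id": sample_ids}
    for name, (rate_low, rate_high) in params.feature_rates.items():
        rate = np.where(low_group, rate_low, rate_high)
        feat[name] = (r.random(n) < rate).astype(int)
    features = pd.DataFrame(feat)

    truth = {
        "params": _params_to_dict(params),
        "seed": params.seed,
        "latent_d": d.tolist(),
        "true_activity": {TF1: a1.tolist(), TF2: a2.tolist()},
        "true_maa": maa_true.tolist(),
        "regulons": {
            TF1: {
                g: {"mode": float(m), "weight": float(w)}
                for g, m, w in zip(targets1, modes1, weights1)
            },
            TF2: {
                g: {"mode": float(m), "weight": float(w)}
                for g, m, w in zip(targets2, modes2, weights2)
            },
        },
        "censoring_tau": {"os": tau_os, "rfs": tau_rfs},
        "low_group_fraction": float(np.mean(low_group)),
    }
    return SyntheticCohort(
        expression=expression,
        isoform_map=isoform_map,
        clinical=clinical,
        features=features,
        truth=truth,
    )


def _params_to_dict(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    d["weight_range"] = list(d["weight_range"])
    return d


TRUTH_FIELDS = ("latent_d", "true_activity", "true_maa", "regulons")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, force: bool = False):
    """Write expression/clinical/features TSVs plus a quarantined truth JSON.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise CohortError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(cohort.expression, out / "expression.tsv")
    with open(out / "isoform_map.tsv", "w") as fh:
        for iso, gene in cohort.isoform_map.mapping.items():
            fh.write(f"{iso}\t{gene}\n")
    write_clinical(cohort.clinical, out / "clinical.tsv")
    cohort.features.to_csv(out / "features.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return {
        "expression": out / "expression.tsv",
        "isoform_map": out / "isoform_map.tsv",
        "clinical": out / "clinical.tsv",
        "features": out / "features.tsv",
        "truth": out / "truth.json",
    }
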