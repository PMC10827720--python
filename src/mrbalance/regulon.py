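"""Mutual-information regulon inference for designated regulator isoforms.

The estimator is deterministic and rank-based: both vectors are rank
transformed, discretized into equal-frequency bins (``B = max(2,
floor(sqrt(n/5)))``) and the plug-in mutual information of the resulting
contingency table is computed in nats, with a Miller-Madow bias correction
over occupied cells.  Rank transformation makes the estimate exactly
invariant under strictly monotone maps of either argument.

Significance is calibrated against a pooled permutation null.  Because the
screening thresholds of interest are far below ``1/n_perm``, an exponential
tail fitted to the top 5% of the null samples extrapolates p-values beyond
the observed null range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

TAIL_FRACTION = 0.05  # upper quantile of null samples used for the tail fit


class RegulonError(ValueError):
    """Raised on invalid regulon-inference inputs."""


@dataclass(frozen=True)
class RegulonConfig:
    """Knobs of the regulon-inference stage.

    ``alpha`` is the per-target significance bound (defaults to the extreme
    screening threshold used for the published networks); ``top_k``, when
    set, keeps the k highest-MI candidates instead of thresholding on p.
    ``dpi_epsilon`` is reserved: data-processing-inequality pruning is not
    applied.
    """

    alpha: float = 1e-130
    n_perm: int = 1000
    min_regulon_size: int = 10
    seed: int = 0
    top_k: int | None = None
    dpi_epsilon: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise RegulonError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise RegulonError("n_perm must be >= 100")


@dataclass(frozen=True)
class TargetCandidate:
    gene_id: str
    mi: float
    p_value: float

    def __post_init__(self) -> None:
        if self.mi < 0:
            raise RegulonError("mi must be >= 0")
        if not 0 <= self.p_value <= 1:
            raise RegulonError("p_value must be in [0, 1]")


@dataclass(frozen=True)
class RegulonTarget:
    gene_id: str
    mode: float  # sign of regulation, in [-1, 1], nonzero
    weight: float  # confidence weight in (0, 1]
    mi: float
    p_value: float


@dataclass
class Regulon:
    """A regulator's target set with per-target mode, weight, MI and p."""

    tf_id: str
    targets: list[RegulonTarget]

    def __post_init__(self) -> None:
        gene_ids = [t.gene_id for t in self.targets]
        if self.tf_id in gene_ids:
            raise RegulonError(f"regulon of {self.tf_id!r} contains itself")
        if len(set(gene_ids)) != len(gene_ids):
            raise RegulonError("duplicate target gene ids")
        for t in self.targets:
            if not 0 < t.weight <= 1:
                raise RegulonError(f"weight of {t.gene_id!r} outside (0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.targets]

    def __len__(self) -> int:
        return len(self.targets)


def n_bins(n: int) -> int:
    """Equal-frequency bin count: ``max(2, floor(sqrt(n/5)))``."""
    return max(2, int(np.floor(np.sqrt(n / 5.0))))


def _bin_ranks(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins via ranks."""
    r = rankdata(x)  # mid-ranks for ties
    idx = np.minimum(((r - 1) * bins) // len(x), bins - 1).astype(np.intp)
    return idx


def estimate_mi(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-based, bias-corrected plug-in mutual information in nats.

    Deterministic and symmetric; exactly invariant to strictly monotone
    transforms of either argument.  Raises on constant input (the marginal
    entropy is then zero and MI is undefined for this estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RegulonError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 20:
        raise RegulonError(f"need n >= 20 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise RegulonError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RegulonError("MI undefined for a constant vector")

    bins = n_bins(n)
    bx = _bin_ranks(x, bins)
    by = _bin_ranks(y, bins)
    counts = np.zeros((bins, bins), dtype=float)
    np.add.at(counts, (bx, by), 1.0)
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    raw = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    # Miller-Madow correction over occupied cells:
    # (m_xy - m_x - m_y + 1) / (2n) removes the leading plug-in bias.
    m_xy = int(nz.sum())
    m_x = int((px > 0).sum())
    m_y = int((py > 0).sum())
    corrected = raw - (m_xy - m_x - m_y + 1) / (2.0 * n)
    # floor at a vanishing positive fraction of the raw plug-in value:
    # keeps the estimate > 0 without the point mass at zero that a hard
    # clip would create (permutation-null p-values must stay continuous)
    return max(corrected, 1e-9 * raw)


@dataclass
class MINullModel:
    """Pooled permutation null for MI with an exponential upper tail.

    ``samples`` are sorted null MI draws; the tail (location ``tail_loc``,
    scale ``tail_scale``) is an exponential fitted by maximum likelihood to
    the exceedances above the ``1 - TAIL_FRACTION`` quantile.
    """

    samples: np.ndarray
    tail_loc: float
    tail_scale: float
    n_perm: int
    seed: int

    def p_value(self, mi: float) -> float:
        if mi < 0:
            raise RegulonError("mi must be >= 0")
        n = self.samples.size
        # empirical survival with the (k+1)/(n+1) convention
        k = n - int(np.searchsorted(self.samples, mi, side="left"))
        p_emp = (k + 1) / (n + 1)
        if mi <= self.tail_loc:
            return p_emp
        p_tail = TAIL_FRACTION * float(np.exp(-(mi - self.tail_loc) / self.tail_scale))
        # min of two non-increasing functions stays monotone in mi
        return max(min(p_emp, p_tail), 5e-324)


def build_null(
    x: Sequence[float], expr: ExpressionMatrix, config: RegulonConfig
) -> MINullModel:
    """Permutation null: MI of shuffled ``x`` against randomly drawn gene rows."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(config.seed)
    rows = rng.integers(0, expr.n_features, size=config.n_perm)
    samples = np.empty(config.n_perm)
    for i in range(config.n_perm):
        xp = rng.permutation(x)
        row = expr.values[rows[i]]
        if np.ptp(row) == 0:  # constant gene row carries no rank information
            row = rng.standard_normal(x.size)
        samples[i] = estimate_mi(xp, row)
    samples.sort()
    loc = float(np.quantile(samples, 1.0 - TAIL_FRACTION))
    exceed = samples[samples > loc] - loc
    scale = float(exceed.mean()) if exceed.size else 1e-12
    scale = max(scale, 1e-12)
    return MINullModel(
        samples=samples,
        tail_loc=loc,
        tail_scale=scale,
        n_perm=config.n_perm,
        seed=config.seed,
    )


def mi_pvalue(mi: float, null: MINullModel) -> float:
    """P-value of an observed MI under a permutation null model."""
    return null.p_value(mi)


def infer_isoform_targets(
    tf_vector: Sequence[float],
    expr: ExpressionMatrix,
    config: RegulonConfig,
    exclude: Iterable[str] = (),
    null: MINullModel | None = None,
) -> list[TargetCandidate]:
    """Screen every gene of ``expr`` against one regulator isoform.

    Returns candidates with ``p <= alpha`` (or the ``top_k`` highest-MI
    genes when configured), sorted by MI descending.  Genes in ``exclude``
    (the regulator's own gene and isoforms) are never returned.
    """
    tf_vector = np.asarray(tf_vector, dtype=float)
    if np.ptp(tf_vector) == 0:
        raise RegulonError("constant regulator vector")
    if null is None:
        null = build_null(tf_vector, expr, config)
    excluded = set(exclude)
    candidates: list[TargetCandidate] = []
    for gene, row in zip(expr.feature_ids, expr.values):
        if gene in excluded:
            continue
        if np.ptp(row) == 0:
            continue
        mi = estimate_mi(tf_vector, row)
        p = null.p_value(mi)
        candidates.append(TargetCandidate(gene_id=gene, mi=mi, p_value=p))
    candidates.sort(key=lambda c: (-c.mi, c.gene_id))
    if config.top_k is not None:
        return candidates[: config.top_k]
    return [c for c in candidates if c.p_value <= config.alpha]


def annotate_mode_weight(
    tf_vector: Sequence[float],
    expr: ExpressionMatrix,
    candidates: Sequence[TargetCandidate],
    tf_id: str,
) -> Regulon:
    """Attach regulation mode and confidence weight to screened candidates.

    Mode is the sign of the Spearman correlation between the regulator
    vector and the target row; weight is its absolute value clipped to
    (0, 1].  Exactly-zero correlations are dropped with a warning.
    """
    if not candidates:
        raise RegulonError("no candidates to annotate")
    tf_vector = np.asarray(tf_vector, dtype=float)
    targets: list[RegulonTarget] = []
    for cand in candidates:
        rho = spearmanr(tf_vector, expr.row(cand.gene_id)).statistic
        if not np.isfinite(rho) or rho == 0:
            logger.warning(
                "target %s has zero/undefined correlation with %s; dropped",
                cand.gene_id,
                tf_id,
            )
            continue
        targets.append(
            RegulonTarget(
                gene_id=cand.gene_id,
                mode=float(np.sign(rho)),
                weight=float(min(abs(rho), 1.0)),
                mi=cand.mi,
                p_value=cand.p_value,
            )
        )
    return Regulon(tf_id=tf_id, targets=targets)


def union_regulons(per_isoform: Sequence[Regulon], tf_id: str) -> Regulon:
    """Union of per-isoform regulons into one regulator-level regulon.

    For genes occurring in several isoform regulons the entry with the
    largest weight wins (ties: largest MI, then smallest gene ID).
    """
    if not per_isoform:
        raise RegulonError("no regulons to union")
    best: dict[str, RegulonTarget] = {}
    for reg in per_isoform:
        for t in reg.targets:
            cur = best.get(t.gene_id)
            if cur is None or (t.weight, t.mi) > (cur.weight, cur.mi):
                best[t.gene_id] = t
    if not best:
        raise RegulonError("empty union")
    targets = sorted(best.values(), key=lambda t: (-t.mi, t.gene_id))
    return Regulon(tf_id=tf_id, targets=targets)


def infer_regulon(
    isoform_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    tf_id: str,
    isoform_ids: Sequence[str],
    config: RegulonConfig,
    exclude: Iterable[str] = (),
) -> Regulon:
    """End-to-end: per-isoform screens, annotation, and union for one regulator."""
    excluded = set(exclude) | {tf_id} | set(isoform_ids)
    per_isoform = []
    for iso in isoform_ids:
        vec = isoform_matrix.row(iso)
        cands = infer_isoform_targets(vec, gene_matrix, config, exclude=excluded)
        if not cands:
            logger.warning("isoform %s of %s yielded no targets", iso, tf_id)
            continue
        per_isoform.append(annotate_mode_weight(vec, gene_matrix, cands, tf_id))
    if not per_isoform:
        raise RegulonError(f"no isoform of {tf_id!r} yielded any target")
    reg = union_regulons(per_isoform, tf_id)
    if len(reg) < config.min_regulon_size:
        logger.warning(
            "regulon of %s has only %d targets (min %d)",
            tf_id,
            len(reg),
            config.min_regulon_size,
        )
    return reg


REGULON_COLUMNS = ("tf_id", "gene_id", "mode", "weight", "mi", "p_value")


def write_regulon_tsv(regulon: Regulon, path: str | Path) -> None:
    rows = [
        (regulon.tf_id, t.gene_id, t.mode, t.weight, t.mi, t.p_value)
        for t in regulon.targets
    ]
    pd.DataFrame(rows, columns=REGULON_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_regulon_tsv(path: str | Path) -> Regulon:
    df = pd.read_csv(path, sep="\t")
    missing = set(REGULON_COLUMNS) - set(df.columns)
    if missing:
        raise RegulonError(f"regulon file missing columns {sorted(missing)}")
    tf_ids = df["tf_id"].unique()
    if len(tf_ids) != 1:
        raise RegulonError("regulon file must contain exactly one tf_id")
    targets = [
        RegulonTarget(
            gene_id=str(r.gene_id),
            mode=float(r.mode),
            weight=float(r.weight),
            mi=float(r.mi),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]
    return Regulon(tf_id=str(tf_ids[0]), targets=targets)
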