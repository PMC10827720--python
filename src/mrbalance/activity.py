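"""Per-sample regulator activity as rank-enrichment NES of a regulon.

A simplified analytic rank-based enrichment: expression is converted to a
gene-wise quantile signature across the cohort (each gene's values replaced
by standard-normal quantiles of their ranks), and a regulator's activity in
a sample is the weighted, mode-signed mean of its targets' signature scores,
normalized so that NES is asymptotically standard normal under the null.

No three-tail combination and no pleiotropy/shadow correction are applied;
the downstream index only needs the signed activity values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .expression_io import ExpressionMatrix
from .regulon import Regulon

logger = logging.getLogger(__name__)


class ActivityError(ValueError):
    pass


@dataclass
class SignatureMatrix:
    """Gene x sample matrix of quantile scores Phi^-1(rank/(n+1))."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def column(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids)


def rank_signature(mat: ExpressionMatrix) -> SignatureMatrix:
    """Gene-wise rank quantile signature across samples.

    Ties get mid-ranks, so a constant gene row maps to all-zero scores
    (logged).  Each tie-free row has mean exactly 0 by symmetry of the
    normal quantiles.
    """
    if mat.feature_level != "gene":
        raise ActivityError("rank_signature requires a gene-level matrix")
    n = mat.n_samples
    if n < 20:
        raise ActivityError(f"need >= 20 samples, got {n}")
    ranks = np.apply_along_axis(rankdata, 1, mat.values)
    scores = norm.ppf(ranks / (n + 1.0))
    n_const = int(np.sum(np.ptp(mat.values, axis=1) == 0))
    if n_const:
        logger.info("rank_signature: %d constant gene rows scored as zero", n_const)
    return SignatureMatrix(
        gene_ids=list(mat.feature_ids),
        sample_ids=list(mat.sample_ids),
        values=scores,
    )


def compute_nes(
    signature_column: pd.Series, regulon: Regulon, min_overlap: int = 10
) -> float:
    """NES of one regulon on one sample's signature column.

    ``NES = sum_g w_g * m_g * q_g / sqrt(sum_g w_g^2)`` over the regulon
    targets g present in the signature.  Fails loudly when fewer than
    ``min_overlap`` targets are found.
    """
    present = [t for t in regulon.targets if t.gene_id in signature_column.index]
    n_missing = len(regulon.targets) - len(present)
    if len(present) < min_overlap:
        raise ActivityError(
            f"regulon {regulon.tf_id!r}: only {len(present)} targets in the "
            f"signature ({n_missing} missing); need >= {min_overlap}"
        )
    q = signature_column.loc[[t.gene_id for t in present]].to_numpy(dtype=float)
    w = np.array([t.weight for t in present])
    m = np.array([t.mode for t in present])
    return float(np.sum(w * m * q) / np.sqrt(np.sum(w**2)))


@dataclass
class ActivityProfile:
    """Per-sample NES for each regulator."""

    data: pd.DataFrame  # index: sample_id; one column per regulator
    regulon_ids: tuple[str, ...]

    def activity(self, tf_id: str) -> pd.Series:
        return self.data[tf_id]


def activity_matrix(
    mat: ExpressionMatrix, regulons: list[Regulon], min_overlap: int = 10
) -> ActivityProfile:
    """NES of every regulon in every sample of a gene-level matrix."""
    sig = rank_signature(mat)
    gene_index = {g: i for i, g in enumerate(sig.gene_ids)}
    out = np.empty((len(sig.sample_ids), len(regulons)))
    for k, reg in enumerate(regulons):
        rows = [gene_index[t.gene_id] for t in reg.targets if t.gene_id in gene_index]
        present = [t for t in reg.targets if t.gene_id in gene_index]
        if len(present) < min_overlap:
            raise ActivityError(
                f"regulon {reg.tf_id!r}: only {len(present)} targets present "
                f"({len(reg.targets) - len(present)} missing); need >= {min_overlap}"
            )
        w = np.array([t.weight for t in present])
        m = np.array([t.mode for t in present])
        q = sig.values[rows, :]  # targets x samples
        out[:, k] = (w * m) @ q / np.sqrt(np.sum(w**2))
    df = pd.DataFrame(out, index=sig.sample_ids, columns=[r.tf_id for r in regulons])
    df.index.name = "sample_id"
    return ActivityProfile(data=df, regulon_ids=tuple(r.tf_id for r in regulons))


def write_activity_tsv(profile: ActivityProfile, path) -> None:
    profile.data.to_csv(path, sep="\t", float_format="%.12g")


def read_activity_tsv(path) -> ActivityProfile:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return ActivityProfile(data=df, regulon_ids=tuple(df.columns))
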