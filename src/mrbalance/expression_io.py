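"""Reading, aggregation and transformation of expression matrices and clinical tables.

Expression matrices follow the RSEM-isoform TSV dialect: first column holds
feature identifiers (transcript or gene level), remaining columns are one
sample each.  Clinical tables are TSVs with at least ``sample_id``,
``os_time`` and ``os_event`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STAGES = ("I", "II", "IIIA", "IIIB", "IV")

CLINICAL_REQUIRED = ("sample_id", "os_time", "os_event")
CLINICAL_OPTIONAL = ("rfs_time", "rfs_event", "stage", "sex", "age", "pack_years")


class ExpressionIOError(ValueError):
    """Raised on malformed expression or clinical inputs."""


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with feature-level metadata.

    Parameters
    ----------
    feature_ids:
        Transcript or gene identifiers, one per row; unique.
    sample_ids:
        Sample barcodes, one per column; unique.
    values:
        Array of shape ``(len(feature_ids), len(sample_ids))``, finite.
        Non-negative unless ``log_transformed``.
    log_transformed:
        Whether values are on a log2 scale.
    feature_level:
        ``"isoform"`` or ``"gene"``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_transformed: bool = False
    feature_level: str = "gene"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ExpressionIOError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.feature_level not in ("isoform", "gene"):
            raise ExpressionIOError(f"unknown feature_level {self.feature_level!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = pd.Index(self.feature_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ExpressionIOError(f"duplicated feature ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionIOError("duplicated sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionIOError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across samples."""
        try:
            return self.values[self._index[feature_id]]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        cols = [self.sample_ids.index(s) for s in ids]
        return replace(self, sample_ids=ids, values=self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:  # value-based equality
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.log_transformed == other.log_transformed
            and self.feature_level == other.feature_level
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class IsoformMap:
    """Mapping isoform_id -> gene_symbol plus designated regulator isoforms.

    ``tf_isoforms`` maps a regulator's gene symbol to the transcript IDs used
    for that regulator (e.g. the designated dNp63/p40 and TTF1 transcripts).
    Every designated isoform must map to exactly one gene symbol.
    """

    mapping: Mapping[str, str]
    tf_isoforms: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, isos in self.tf_isoforms.items():
            for iso in isos:
                if iso not in self.mapping:
                    raise ExpressionIOError(
                        f"designated isoform {iso!r} of {tf!r} has no gene mapping"
                    )
                if self.mapping[iso] != tf:
                    raise ExpressionIOError(
                        f"designated isoform {iso!r} maps to "
                        f"{self.mapping[iso]!r}, not {tf!r}"
                    )

    def gene_of(self, isoform_id: str) -> str:
        return self.mapping[isoform_id]


def read_isoform_map(path: str | Path) -> IsoformMap:
    """Read a two-column TSV ``isoform_id<TAB>gene_symbol`` (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["isoform_id", "gene"])
    if df.isna().any().any():
        raise ExpressionIOError(f"missing values in isoform map {path}")
    return IsoformMap(dict(zip(df["isoform_id"].astype(str), df["gene"].astype(str))))


def read_expression_matrix(
    path: str | Path, feature_level: str = "gene"
) -> ExpressionMatrix:
    """Read an expression TSV (header: ``feature_id<TAB>sample...``).

    Non-numeric cells raise :class:`ExpressionIOError` naming the offending
    row and column; duplicated feature rows are rejected.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ExpressionIOError(f"empty or missing expression file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionIOError(f"no data rows/columns in {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy())[0]
        if bad.size:
            i = int(bad[0])
            raise ExpressionIOError(
                f"non-numeric cell {df[col].iloc[i]!r} at feature "
                f"{df.index[i]!r}, sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        feature_level=feature_level,
    )


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the same TSV dialect read by :func:`read_expression_matrix`."""
    df = mat.to_frame()
    df.index.name = "feature_id"
    # %.12g keeps round-trips faithful to 12 significant digits
    df.to_csv(path, sep="\t", float_format="%.12g")


def aggregate_to_gene(
    mat: ExpressionMatrix, isoform_map: IsoformMap, rule: str = "sum"
) -> ExpressionMatrix:
    """Collapse an isoform-level matrix to gene level.

    ``rule="sum"`` adds isoform rows elementwise; ``rule="max_variance"``
    keeps, per gene, the single isoform with the largest variance across
    samples (ties broken by the lexicographically smallest isoform ID).
    Unmapped isoforms are dropped with a logged count.
    """
    if mat.feature_level != "isoform":
        raise ExpressionIOError("aggregate_to_gene requires an isoform-level matrix")
    if rule not in ("sum", "max_variance"):
        raise ExpressionIOError(f"unknown aggregation rule {rule!r}")

    mapped_rows: dict[str, list[int]] = {}
    n_dropped = 0
    for i, iso in enumerate(mat.feature_ids):
        gene = isoform_map.mapping.get(iso)
        if gene is None:
            n_dropped += 1
            continue
        mapped_rows.setdefault(gene, []).append(i)
    if n_dropped:
        logger.info("aggregate_to_gene: dropped %d unmapped isoforms", n_dropped)
    if not mapped_rows:
        raise ExpressionIOError("no isoforms in the matrix are covered by the map")

    genes = sorted(mapped_rows)
    out = np.empty((len(genes), mat.n_samples), dtype=float)
    for g, gene in enumerate(genes):
        rows = mapped_rows[gene]
        if rule == "sum":
            out[g] = mat.values[rows].sum(axis=0)
        else:
            variances = mat.values[rows].var(axis=1, ddof=0)
            best = max(
                range(len(rows)),
                key=lambda k: (variances[k], ReverseStr(mat.feature_ids[rows[k]])),
            )
            out[g] = mat.values[rows[best]]
    return ExpressionMatrix(
        feature_ids=genes,
        sample_ids=list(mat.sample_ids),
        values=out,
        log_transformed=mat.log_transformed,
        feature_level="gene",
    )


class ReverseStr(str):
    """String with inverted ordering, used to break variance ties toward
    the smallest isoform ID inside a single ``max()`` key."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str(self) > str(other)

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str(self) < str(other)


def log_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a copy with values mapped through ``log2(v + pseudocount)``."""
    if mat.log_transformed:
        raise ExpressionIOError("matrix is already log-transformed")
    if pseudocount <= 0:
        raise ExpressionIOError("pseudocount must be positive")
    if np.any(mat.values < 0):
        raise ExpressionIOError("negative values cannot be log-transformed")
    return replace(
        mat, values=np.log2(mat.values + pseudocount), log_transformed=True
    )


def normalize_stage(raw: object) -> str | None:
    """Normalize a pathological-stage string to the controlled vocabulary.

    Case-insensitive, whitespace-tolerant; "Stage" prefixes are stripped and
    A/B sub-stages of I and II are collapsed to the main stage.  Unknown
    strings map to ``None`` with a warning.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).upper().replace(" ", "").replace("\t", "")
    if s.startswith("STAGE"):
        s = s[5:]
    if s in ("IA", "IB"):
        s = "I"
    elif s in ("IIA", "IIB"):
        s = "II"
    elif s == "IVA" or s == "IVB":
        s = "IV"
    if s in VALID_STAGES:
        return s
    if s in ("", "NA", "NAN", "NONE", "UNKNOWN", "[NOTAVAILABLE]"):
        return None
    logger.warning("unknown stage %r mapped to missing", raw)
    return None


@dataclass
class ClinicalTable:
    """Typed clinical table with survival endpoints and covariates.

    ``data`` columns: sample_id, os_time, os_event, rfs_time, rfs_event,
    stage, sex, age, pack_years (optional ones may be absent/NaN).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in CLINICAL_REQUIRED:
            if col not in self.data.columns:
                raise ExpressionIOError(f"clinical table missing column {col!r}")
        times = self.data["os_time"].dropna()
        if (times < 0).any():
            raise ExpressionIOError("negative os_time")
        events = self.data["os_event"].dropna()
        if not events.isin([0, 1]).all():
            bad = sorted(events[~events.isin([0, 1])].unique())
            raise ExpressionIOError(f"os_event must be 0/1, found {bad}")
        if "rfs_event" in self.data.columns:
            rfs = self.data["rfs_event"].dropna()
            if not rfs.isin([0, 1]).all():
                raise ExpressionIOError("rfs_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV, normalizing stage labels and flagging rows
    without survival status."""
    df = pd.read_csv(path, sep="\t")
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise ExpressionIOError(f"clinical file {path} missing column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    n_missing = int(df["os_event"].isna().sum() + df["os_time"].isna().sum())
    if n_missing:
        logger.warning("%d rows lack survival status/time", n_missing)
    if "stage" in df.columns:
        df["stage"] = df["stage"].map(normalize_stage)
    for col in ("rfs_time", "rfs_event", "age", "pack_years"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
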