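"""Zasp isoform classification and class-wise expression time courses.

Alp/Enigma-family Zasp proteins carry an α-actinin-binding PDZ domain, a
ZM motif, and zero to four LIM domains. Isoforms with two or more LIM
domains recruit further Zasp molecules and enlarge the Z-disc ("growing"
isoforms); isoforms with zero or one LIM domain cap recruitment
("blocking" isoforms). :func:`classify_isoform` applies exactly that
boundary; :func:`class_timecourse` summarizes a transcript×timepoint TPM
matrix per class over pupal development (hours APF), and
:func:`onset_time` extracts a half-plateau onset time from a class mean
trajectory.

Log display uses log10(TPM + 1): bounded at zero and standard for TPM
scales; the pseudocount and base are recorded with the outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IsoformRecord",
    "IsoformExpressionSet",
    "ClassTimecourse",
    "classify_isoform",
    "class_timecourse",
    "onset_time",
    "load_expression_set",
]

GROWING = "growing"
BLOCKING = "blocking"

#: smallest LIM-domain count classified as growing
GROWING_MIN_LIM = 2


@dataclass
class IsoformRecord:
    """Domain architecture of one annotated transcript."""

    transcript_id: str
    gene: str = "other"
    n_lim: int = 0
    has_zm: bool = True
    has_pdz: bool = False

    def __post_init__(self) -> None:
        if self.n_lim < 0:
            raise ValueError("n_lim must be >= 0")


@dataclass
class IsoformExpressionSet:
    """TPM matrix (transcripts × timepoints in hours APF) plus annotations.

    ``tpm`` is indexed by transcript id with float timepoint columns;
    ``records`` is a DataFrame with columns transcript_id, gene, n_lim,
    has_zm, has_pdz, one row per tpm row, same order not required but the
    id sets must match one-to-one.
    """

    tpm: pd.DataFrame
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tpm.empty:
            raise ValueError("expression set is empty")
        t = np.asarray(self.tpm.columns, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.tpm.to_numpy() < 0):
            raise ValueError("TPM values must be >= 0")
        ids = set(self.tpm.index)
        rec_ids = set(self.records["transcript_id"])
        if ids != rec_ids or len(self.records) != len(self.tpm):
            raise ValueError("tpm rows and isoform records must match one-to-one")

    @property
    def timepoints_h(self) -> np.ndarray:
        return np.asarray(self.tpm.columns, dtype=float)


@dataclass
class ClassTimecourse:
    """Per-class mean expression over developmental time."""

    class_label: str
    timepoints_h: np.ndarray
    mean_tpm: np.ndarray
    mean_log_tpm: np.ndarray  # log10(mean TPM + 1)
    n_isoforms: int


def classify_isoform(record: IsoformRecord | pd.Series | dict) -> str:
    """Growing iff the isoform has two or more LIM domains, else blocking."""
    n_lim = record.n_lim if isinstance(record, IsoformRecord) else record["n_lim"]
    if n_lim < 0:
        raise ValueError("n_lim must be >= 0")
    return GROWING if n_lim >= GROWING_MIN_LIM else BLOCKING


def class_timecourse(
    expr: IsoformExpressionSet, by_gene: bool = False
) -> list[ClassTimecourse]:
    """Mean TPM per isoform class and timepoint.

    Transcripts are grouped by :func:`classify_isoform` (optionally further
    split by gene with ``by_gene``); per class and timepoint the mean TPM
    is computed and also reported as log10(mean + 1). Classes with zero
    members are omitted with a warning.
    """
    recs = expr.records.set_index("transcript_id")
    classes = recs["n_lim"].apply(lambda n: GROWING if n >= GROWING_MIN_LIM else BLOCKING)
    t = expr.timepoints_h
    out: list[ClassTimecourse] = []
    if by_gene:
        keys = sorted(set(zip(recs.loc[expr.tpm.index, "gene"], classes.loc[expr.tpm.index])))
        groups = [
            (f"{g}:{c}", expr.tpm.index[(recs.loc[expr.tpm.index, "gene"] == g).to_numpy()
                                        & (classes.loc[expr.tpm.index] == c).to_numpy()])
            for g, c in keys
        ]
    else:
        groups = [
            (c, expr.tpm.index[(classes.loc[expr.tpm.index] == c).to_numpy()])
            for c in (GROWING, BLOCKING)
        ]
    for label, ids in groups:
        if len(ids) == 0:
            warnings.warn(f"class {label!r} has no members; omitted", stacklevel=2)
            continue
        mean = expr.tpm.loc[ids].mean(axis=0).to_numpy(dtype=float)
        out.append(
            ClassTimecourse(
                class_label=label,
                timepoints_h=t,
                mean_tpm=mean,
                mean_log_tpm=np.log10(mean + 1.0),
                n_isoforms=len(ids),
            )
        )
    return out


def onset_time(tc: ClassTimecourse, fraction_of_plateau: float = 0.5) -> float | None:
    """Time at which a class mean first crosses a fraction of its plateau.

    Linear interpolation between the bracketing timepoints. A flat
    trajectory has no onset and returns None. A trajectory that is not
    non-decreasing up to its plateau triggers a warning (the crossing is
    still reported).
    """
    if not (0 < fraction_of_plateau < 1):
        raise ValueError("fraction_of_plateau must be in (0, 1)")
    y = np.asarray(tc.mean_tpm, dtype=float)
    t = np.asarray(tc.timepoints_h, dtype=float)
    peak = y.max()
    if peak <= 0 or np.allclose(y, y[0]):
        return None
    imax = int(np.argmax(y))
    if np.any(np.diff(y[: imax + 1]) < -0.05 * peak):
        warnings.warn(
            f"class {tc.class_label!r} time course is not monotone up to its plateau",
            stacklevel=2,
        )
    target = fraction_of_plateau * peak
    above = np.nonzero(y >= target)[0]
    i = int(above[0])
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


def example_isoform_records() -> pd.DataFrame:
    """A small illustrative Zasp isoform annotation table.

    Domain counts follow well-known representatives (Zasp52-PR with a PDZ,
    a ZM and 4 LIM domains; Zasp52-PK with a single LIM; Zasp66/Zasp67
    without LIM domains); it is an illustration of the input format, not a
    curated genome annotation.
    """
    return pd.DataFrame(
        [
            {"transcript_id": "Zasp52-PR", "gene": "Zasp52", "n_lim": 4, "has_zm": True, "has_pdz": True},
            {"transcript_id": "Zasp52-PE", "gene": "Zasp52", "n_lim": 3, "has_zm": True, "has_pdz": True},
            {"transcript_id": "Zasp52-PK", "gene": "Zasp52", "n_lim": 1, "has_zm": True, "has_pdz": True},
            {"transcript_id": "Zasp66-PH", "gene": "Zasp66", "n_lim": 0, "has_zm": True, "has_pdz": True},
            {"transcript_id": "Zasp67-RA", "gene": "Zasp67", "n_lim": 0, "has_zm": True, "has_pdz": False},
        ]
    )


def load_expression_set(annotation_csv, tpm_csv) -> IsoformExpressionSet:
    """Load an isoform-annotation CSV and a TPM table into an expression set.

    The annotation table needs columns transcript_id, gene, n_lim, has_zm,
    has_pdz; the TPM table has transcript ids in its first column and a
    header row of timepoints in hours APF (CSV or TSV, sniffed by pandas).
    """
    records = pd.read_csv(annotation_csv)
    required = {"transcript_id", "gene", "n_lim", "has_zm", "has_pdz"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    tpm = pd.read_csv(tpm_csv, sep=None, engine="python", index_col=0)
    tpm.columns = [float(c) for c in tpm.columns]
    return IsoformExpressionSet(tpm=tpm, records=records)
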