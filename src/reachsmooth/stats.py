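"""Rank correlation, split-half ICC, group summaries, and the packaged
clinical dataset used in the worked examples.

The packaged table holds the published two-session assessment of 13
chronic stroke patients (P1-P13) and one healthy volunteer (H1)
performing the repetitive lap-to-mouth reach: ordinal SIAS Knee-Mouth
scores (0-5), the 54-point upper-extremity Fugl-Meyer subset (FMA-UE),
modified Ashworth elbow scores, and the two kinematic smoothness
metrics — MedianLC (MLC) and the session-mean log MSJ ratio (LMSJR).
FMA-UE/MAS are missing for P10 and the MSJ ratio for P4 (whose
continuous movement could not be segmented); missing values are handled
by pairwise deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    AlignmentError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

IccForm = Literal["icc_2_1", "icc_1_1"]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs containing a missing value (None/NaN) are deleted pairwise.
    rho is the Pearson correlation of the average-rank vectors, the
    standard tie-corrected definition.
    """
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if len(xa) != len(ya):
        raise AlignmentError(f"length mismatch: {len(xa)} vs {len(ya)}")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise InsufficientDataError(
            f"only {len(xa)} complete pairs (need >= 3)"
        )
    rx, ry = rankdata(xa), rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero rank variance; rho undefined")
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def split_half_icc(
    first: Sequence[float],
    second: Sequence[float],
    form: IccForm = "icc_2_1",
) -> float:
    """Intraclass correlation between two measurements per subject.

    ``icc_2_1`` (default): two-way random effects, single measurement,
    absolute agreement —

        ICC = (MSR - MSE) / (MSR + MSE + 2 (MSC - MSE) / n)

    with MSR/MSC/MSE the between-subject, between-measurement and
    residual mean squares. Appropriate for test-retest of one
    instrument, where systematic shifts between the two halves should
    count against agreement. ``icc_1_1`` is the one-way form
    (MSR - MSW) / (MSR + MSW), which folds measurement effects into the
    within-subject error.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError(f"halves must be equal-length 1D, got {a.shape} vs {b.shape}")
    n = len(a)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 subjects, got {n}")
    m = np.column_stack([a, b])
    k = 2
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    grand = m.mean()
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )
    if form == "icc_2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            return 1.0 if msr == mse else float("nan")
        return float((msr - mse) / denom)
    if form == "icc_1_1":
        msw = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        if denom == 0:
            return 1.0 if msr == msw else float("nan")
        return float((msr - msw) / denom)
    raise ValidationError(f"unknown ICC form {form!r}")


# ---------------------------------------------------------------------------
# packaged clinical dataset


@dataclass(frozen=True)
class ClinicalTable:
    """Long-format clinical table: one row per participant per session."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"participant_id", "session", "sias_km", "fma_ue",
                    "mas_elbow", "mlc", "lmsjr"}
        if not required <= set(self.frame.columns):
            raise ValidationError(
                f"clinical table missing columns {required - set(self.frame.columns)}"
            )
        counts = self.frame.groupby("session").size()
        if not (counts == counts.iloc[0]).all():
            raise ValidationError("sessions have unequal participant counts")

    def session(self, which: str, include_h1: bool = True) -> pd.DataFrame:
        """Rows of one session, ordered by participant, optionally without H1."""
        df = self.frame[self.frame["session"] == which]
        if not include_h1:
            df = df[df["participant_id"] != "H1"]
        return df.reset_index(drop=True)

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.frame["participant_id"]))


def load_clinical_table() -> ClinicalTable:
    """Load the packaged 14-participant x 2-session assessment table."""
    with resources.files("reachsmooth.data").joinpath(
        "clinical_table.csv"
    ).open() as fh:
        df = pd.read_csv(fh, dtype={"mas_elbow": "string"})
    return ClinicalTable(frame=df)


def group_summary(
    table: ClinicalTable,
    session: str,
    stat: Literal["median", "mean"] = "median",
    metric: str = "mlc",
) -> Mapping[int, float]:
    """Per-SIAS-score summary of a metric over the patients of one session.

    The healthy volunteer H1 is excluded from the patient score groups
    (it anchors the top of the scale and is reported separately).
    """
    df = table.session(session, include_h1=False)
    grouped = df.groupby("sias_km")[metric]
    agg = grouped.median() if stat == "median" else grouped.mean()
    return {int(score): float(v) for score, v in agg.dropna().items()}


#: the published correlation pairs: name -> (session, column_a, column_b)
CORRELATION_PAIRS: dict[str, tuple[str, str, str]] = {
    "mlc_vs_sias_initial": ("initial", "mlc", "sias_km"),
    "mlc_vs_sias_final": ("final", "mlc", "sias_km"),
    "mlc_vs_fma_initial": ("initial", "mlc", "fma_ue"),
    "mlc_vs_fma_final": ("final", "mlc", "fma_ue"),
    "lmsjr_vs_sias_initial": ("initial", "lmsjr", "sias_km"),
    "lmsjr_vs_sias_final": ("final", "lmsjr", "sias_km"),
    "lmsjr_vs_fma_initial": ("initial", "lmsjr", "fma_ue"),
    "lmsjr_vs_fma_final": ("final", "lmsjr", "fma_ue"),
    "mlc_vs_lmsjr_initial": ("initial", "mlc", "lmsjr"),
    "mlc_vs_lmsjr_final": ("final", "mlc", "lmsjr"),
}


#: published values the packaged table should reproduce: name -> (value, tol).
#: Correlation tolerances (+-0.015) absorb the 2-decimal rounding of the
#: table entries and the P7/P13 MedianLC tie at 5.11; medians/means carry
#: the table's own 2-decimal printing tolerance.
PUBLISHED_VALUES: dict[str, tuple[float, float]] = {
    "mlc_vs_sias_initial": (0.842, 0.015),
    "mlc_vs_sias_final": (0.733, 0.015),
    "mlc_vs_fma_initial": (0.753, 0.015),
    "mlc_vs_fma_final": (0.747, 0.015),
    "lmsjr_vs_sias_initial": (-0.769, 0.015),
    "lmsjr_vs_sias_final": (-0.700, 0.015),
    "lmsjr_vs_fma_initial": (-0.797, 0.015),
    "lmsjr_vs_fma_final": (-0.643, 0.015),
    "mlc_vs_lmsjr_initial": (-0.659, 0.015),
    "mlc_vs_lmsjr_final": (-0.895, 0.015),
    "median_mlc_initial_sias2": (3.99, 0.01),
    "median_mlc_initial_sias3": (4.81, 0.01),
    "median_mlc_initial_sias4": (5.11, 0.01),
    "mean_mlc_initial_sias3": (4.76, 0.01),
    "icc_mlc_between_sessions": (0.881, 0.01),
}


def clinical_worked_example(include_h1: bool = True) -> dict[str, float]:
    """Recompute every published summary statistic from the packaged table.

    Returns the correlations of :func:`clinical_correlations`, the
    per-SIAS-group initial-session MedianLC medians, the SIAS-3 group
    mean, and the between-session ICC(2,1) of MedianLC over all 14
    participants.
    """
    table = load_clinical_table()
    out = dict(clinical_correlations(table, include_h1=include_h1))
    medians = group_summary(table, "initial", stat="median")
    means = group_summary(table, "initial", stat="mean")
    for score in (2, 3, 4):
        out[f"median_mlc_initial_sias{score}"] = medians[score]
    out["mean_mlc_initial_sias3"] = means[3]
    ini = table.session("initial", include_h1=True)["mlc"].to_numpy()
    fin = table.session("final", include_h1=True)["mlc"].to_numpy()
    out["icc_mlc_between_sessions"] = split_half_icc(ini, fin)
    return out


def clinical_correlations(
    table: ClinicalTable, include_h1: bool = True
) -> dict[str, float]:
    """All published Spearman correlations recomputed from the table.

    H1 is included by default, matching the published scatter plots of
    "the 13 patients and the healthy volunteer"; missing values (P10's
    FMA/MAS, P4's MSJ ratio) are removed pairwise.
    """
    out = {}
    for name, (session, col_a, col_b) in CORRELATION_PAIRS.items():
        df = table.session(session, include_h1=include_h1)
        out[name] = spearman_rho(df[col_a].tolist(), df[col_b].tolist())
    return out
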