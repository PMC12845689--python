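"""Per-subject AF indices, a threshold classifier, and cohort reporting.

Three index families separate atrial fibrillation from non-AF subjects in
an at-rest PPG segment:

1. across-harmonic HR spread: ``SD(HR)`` and ``SD(HR_phi)``;
2. per-harmonic HRV: ``RMSE(HR_i)`` and ``RMSE(HR_phi_i)``;
3. per-harmonic respiration modulation: ``mean(B_phi_i)``.

The classifier is deliberately simple: one configured cut per family and a
combination rule (majority by default).  Thresholds are configuration, not
learned -- group separation is demonstrated by non-overlapping ranges, so
no training machinery is warranted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cardiometrics import CardiacMetrics
from .reconstruct import Reconstruction
from .respmetrics import RespMetrics

__all__ = [
    "SubjectIndices",
    "Thresholds",
    "compute_indices",
    "classify",
    "cohort_report",
    "INDEX_COLUMNS",
]


@dataclass
class SubjectIndices:
    """The scalar screening indices extracted from one record segment."""

    subject_id: str = ""
    label: str | None = None  # optional ground truth: "AF" | "non-AF"
    hr: float = math.nan  # bpm
    sd_hr: float = math.nan  # bpm
    hr_phi: float = math.nan  # bpm
    sd_hr_phi: float = math.nan  # bpm
    rmse_hr: np.ndarray = field(default_factory=lambda: np.array([]))  # bpm x N
    rmse_hr_phi: np.ndarray = field(default_factory=lambda: np.array([]))  # bpm x N
    mean_b_phi: np.ndarray = field(default_factory=lambda: np.array([]))  # Hz x N
    rr_phi: np.ndarray = field(default_factory=lambda: np.array([]))  # Hz x N
    rmssd_x0: float = math.nan  # bpm
    rmssd_x1: float = math.nan  # bpm
    amp_ratio: np.ndarray = field(default_factory=lambda: np.array([]))
    phase_diff: np.ndarray = field(default_factory=lambda: np.array([]))
    phi3_gt_phi2: bool | None = None


@dataclass
class Thresholds:
    """Classifier cut points (one per index family) and combination rule.

    Defaults: the HR-spread cut is the geometric mean of the reported group
    extremes for SD(HR) (0.23 vs 0.023 bpm); the HRV and RM cuts sit at the
    geometric means of the generator presets' boundary values
    (60*B/sqrt(2) with B = 0.04 / 0.05 Hz, and 2*B respectively).
    """

    sd_hr_cut: float = 0.073  # bpm
    rmse_hr_phi_cut: float = 1.9  # bpm
    b_phi_cut: float = 0.09  # Hz
    rule: str = "majority"  # "majority" | "any-of" | "all-of"

    def __post_init__(self) -> None:
        if min(self.sd_hr_cut, self.rmse_hr_phi_cut, self.b_phi_cut) <= 0:
            raise ValueError("thresholds must be positive")
        if self.rule not in ("majority", "any-of", "all-of"):
            raise ValueError(f"unknown combination rule {self.rule!r}")


def compute_indices(
    cardiac: CardiacMetrics,
    resp: RespMetrics,
    recon: Reconstruction,
    subject_id: str = "",
    label: str | None = None,
) -> SubjectIndices:
    """Collate the screening indices from the stage outputs (pure collation)."""
    return SubjectIndices(
        subject_id=subject_id,
        label=label,
        hr=cardiac.hr,
        sd_hr=cardiac.sd_hr,
        hr_phi=cardiac.hr_phi,
        sd_hr_phi=cardiac.sd_hr_phi,
        rmse_hr=np.asarray(cardiac.rmse_hr, dtype=float),
        rmse_hr_phi=np.asarray(cardiac.rmse_hr_phi, dtype=float),
        mean_b_phi=np.asarray(resp.rm_means, dtype=float),
        rr_phi=np.asarray(resp.rr_phi_means, dtype=float),
        rmssd_x0=cardiac.rmssd.get("x0", math.nan),
        rmssd_x1=cardiac.rmssd.get("x1", math.nan),
        amp_ratio=np.asarray(recon.amp_ratio, dtype=float),
        phase_diff=np.asarray(recon.phase_diff, dtype=float),
        phi3_gt_phi2=recon.phi3_gt_phi2,
    )


def _family_votes(idx: SubjectIndices, thr: Thresholds) -> dict[str, bool | None]:
    """Per-family AF votes; None when the index is unavailable."""
    v1 = None if math.isnan(idx.sd_hr) else idx.sd_hr > thr.sd_hr_cut
    finite_rmse = idx.rmse_hr_phi[np.isfinite(idx.rmse_hr_phi)]
    v2 = None if finite_rmse.size == 0 else float(np.min(finite_rmse)) > thr.rmse_hr_phi_cut
    finite_rm = idx.mean_b_phi[np.isfinite(idx.mean_b_phi)]
    v3 = None if finite_rm.size == 0 else float(np.mean(finite_rm)) > thr.b_phi_cut
    return {"hr_spread": v1, "hrv": v2, "resp_modulation": v3}


def classify(
    idx: SubjectIndices, thr: Thresholds | None = None
) -> tuple[str, dict[str, bool | None]]:
    """Threshold classification: returns ("AF" | "non-AF" | "abstain", votes)."""
    thr = thr or Thresholds()
    votes = _family_votes(idx, thr)
    cast = [v for v in votes.values() if v is not None]
    if not cast:
        return "abstain", votes
    n_af = sum(cast)
    if thr.rule == "any-of":
        decision = n_af >= 1
    elif thr.rule == "all-of":
        decision = n_af == len(cast)
    else:  # majority
        decision = n_af * 2 > len(cast)
    return ("AF" if decision else "non-AF"), votes


INDEX_COLUMNS = (
    "hr",
    "sd_hr",
    "hr_phi",
    "sd_hr_phi",
    "min_rmse_hr",
    "min_rmse_hr_phi",
    "mean_b_phi",
    "mean_rr_phi",
    "rmssd_x0",
    "rmssd_x1",
)


def _row(idx: SubjectIndices) -> dict:
    def _safe(arr: np.ndarray, fn) -> float:
        finite = arr[np.isfinite(arr)] if arr.size else arr
        return float(fn(finite)) if finite.size else math.nan

    return {
        "subject_id": idx.subject_id,
        "label": idx.label,
        "hr": idx.hr,
        "sd_hr": idx.sd_hr,
        "hr_phi": idx.hr_phi,
        "sd_hr_phi": idx.sd_hr_phi,
        "min_rmse_hr": _safe(idx.rmse_hr, np.min),
        "min_rmse_hr_phi": _safe(idx.rmse_hr_phi, np.min),
        "mean_b_phi": _safe(idx.mean_b_phi, np.mean),
        "mean_rr_phi": _safe(idx.rr_phi, np.mean),
        "rmssd_x0": idx.rmssd_x0,
        "rmssd_x1": idx.rmssd_x1,
        "phi3_gt_phi2": idx.phi3_gt_phi2,
    }


def cohort_report(
    indices: list[SubjectIndices],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject table and per-group summary with overlap flags.

    The summary gives mean / SD / median / min / max of every index per
    label group; when both groups are present each index additionally gets
    a ``non_overlapping`` flag (disjoint [min, max] ranges).
    """
    if not indices:
        raise ValueError("need at least one subject")
    table = pd.DataFrame([_row(i) for i in indices])
    group_key = table["label"].fillna("unlabelled")
    summary = (
        table.groupby(group_key)[list(INDEX_COLUMNS)]
        .agg(["mean", "std", "median", "min", "max"])
        .T
    )
    groups = sorted(group_key.unique())
    if {"AF", "non-AF"}.issubset(groups):
        flags = {}
        for col in INDEX_COLUMNS:
            af = table.loc[group_key == "AF", col].dropna()
            non = table.loc[group_key == "non-AF", col].dropna()
            if len(af) and len(non):
                flags[col] = bool(af.min() > non.max() or non.min() > af.max())
            else:
                flags[col] = False
        summary = summary.astype(object)
        for col, flag in flags.items():
            summary.loc[(col, "non_overlapping"), :] = flag
        summary = summary.sort_index()
    return table, summary
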