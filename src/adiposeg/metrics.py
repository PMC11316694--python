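"""Per-subject segmentation metrics, volume quantification, cohort
agreement statistics and the group-comparison statistics layer.

Per-subject metrics follow the evaluation used for abdominal SAT/VAT
segmentation studies: 3D Dice per tissue plus false-positive and
false-negative percentages pooled over the two adipose classes,

    FP = 100 * sum_l sum_n I(r_ln = 0 and p_ln = 1) / sum_l sum_n I(r_ln = 0)
    FN = 100 * sum_l sum_n I(r_ln = 1 and p_ln = 0) / sum_l sum_n I(r_ln = 1)

with l in {SAT, VAT}, so a SAT voxel predicted as VAT counts toward SAT's
FN and VAT's FP.  Volume agreement uses linear regression and the
intraclass correlation coefficient (two-way random effects, absolute
agreement, single measurement by default) with the conventional
poor/moderate/good/excellent categories at 0.5 / 0.75 / 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SAT, VAT, SegMask

log = logging.getLogger(__name__)

ADIPOSE_LABELS = (SAT, VAT)

__all__ = [
    "dice3d", "fp_fn_rates", "mask_volume", "icc_agreement", "icc_category",
    "AgreementResult", "MetricsReport", "delta_volume_analysis",
    "kruskal_wallis", "wilcoxon_signed_rank", "benjamini_hochberg",
    "evaluate_masks",
]


def _labels(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, SegMask) else np.asarray(mask)


def _check_same_grid(pred, ref):
    p, r = _labels(pred), _labels(ref)
    if p.shape != r.shape:
        raise ValueError(f"grid mismatch: prediction {p.shape} vs "
                         f"reference {r.shape}")
    return p, r


def dice3d(pred, ref, class_label: int) -> float:
    """Hard-label 3D Dice 2|P∩R| / (|P|+|R|) over the whole volume.

    Both masks empty for the class is perfect agreement on absence and is
    defined as 1 (logged when triggered).
    """
    p, r = _check_same_grid(pred, ref)
    pm, rm = p == class_label, r == class_label
    denom = pm.sum() + rm.sum()
    if denom == 0:
        log.warning("dice3d: class %d empty in both masks; returning 1.0",
                    class_label)
        return 1.0
    return float(2.0 * np.logical_and(pm, rm).sum() / denom)


def _adipose_indicators(mask):
    """Per-class indicator channels for SAT and VAT.

    Accepts a 3-label volume (SegMask or 3D array) or a pre-stacked
    (n_classes, ...) indicator array — the latter permits predictions
    marking a voxel positive in more than one class, exactly as the
    indicator-based FP/FN definitions allow.
    """
    x = _labels(mask)
    if x.ndim == 4:
        return [np.asarray(x[l], bool) for l in ADIPOSE_LABELS]
    return [x == l for l in ADIPOSE_LABELS]


def fp_fn_rates(pred, ref) -> tuple[float, float]:
    """FP% and FN% pooled over SAT and VAT one-hot channels."""
    p_ind = _adipose_indicators(pred)
    r_ind = _adipose_indicators(ref)
    if p_ind[0].shape != r_ind[0].shape:
        raise ValueError(f"grid mismatch: prediction {p_ind[0].shape} vs "
                         f"reference {r_ind[0].shape}")
    fp_num = fp_den = fn_num = fn_den = 0
    for pl, rl in zip(p_ind, r_ind):
        fp_num += int(np.logical_and(~rl, pl).sum())
        fp_den += int((~rl).sum())
        fn_num += int(np.logical_and(rl, ~pl).sum())
        fn_den += int(rl.sum())
    if fp_den == 0:
        log.warning("fp_fn_rates: no reference-negative voxels; FP := 0")
        fp = 0.0
    else:
        fp = 100.0 * fp_num / fp_den
    if fn_den == 0:
        log.warning("fp_fn_rates: no reference-positive voxels; FN := 0")
        fn = 0.0
    else:
        fn = 100.0 * fn_num / fn_den
    return fp, fn


def mask_volume(mask, class_label: int,
                voxel_size_mm: tuple[float, float, float] | None = None
                ) -> float:
    """Voxel-count volume in mL: count * dx*dy*dz / 1000."""
    if voxel_size_mm is None:
        if not isinstance(mask, SegMask):
            raise ValueError("voxel_size_mm required for a bare array")
        voxel_size_mm = mask.voxel_size_mm
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    count = int((_labels(mask) == class_label).sum())
    dx, dy, dz = voxel_size_mm
    return count * dx * dy * dz / 1000.0


# ---------------------------------------------------------------------------
# agreement

def icc_category(icc: float) -> str:
    """Poor < 0.5; moderate 0.5-0.75; good 0.75-0.9; excellent > 0.9."""
    if np.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


@dataclass
class AgreementResult:
    icc: float
    category: str
    slope: float
    intercept: float
    variant: str = "ICC2"

    def __str__(self):
        return (f"ICC({self.variant}) = {self.icc:.4f} ({self.category}); "
                f"regression b = {self.slope:.3f} a + {self.intercept:.2f}")


def icc_agreement(series_a, series_b, variant: str = "ICC2"
                  ) -> AgreementResult:
    """Agreement between two measurement series of the same subjects.

    ``variant`` is a pingouin ICC type code: ICC2 (two-way random effects,
    absolute agreement, single measurement; the default, because bias
    between methods matters for volume quantification) or ICC3
    (consistency).  Regression is of b on a.
    """
    import pingouin as pg

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1D series with n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and not np.array_equal(a, b):
        log.warning("icc_agreement: zero variance in both series; "
                    "ICC undefined")
        return AgreementResult(np.nan, "undefined", np.nan, np.nan, variant)
    slope, intercept = np.polyfit(a, b, 1) if np.ptp(a) > 0 else (np.nan,
                                                                  np.nan)
    if np.array_equal(a, b):
        # perfect agreement; the ANOVA ratio is 1 by definition
        return AgreementResult(1.0, icc_category(1.0), 1.0, 0.0, variant)
    n = a.size
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["a", "b"], n),
        "score": np.concatenate([a, b]),
    })
    table = pg.intraclass_corr(df, targets="targets", raters="raters",
                               ratings="score")
    # pingouin labels rows by McGraw-Wong convention: ICC(A,1) is the
    # two-way absolute-agreement single-measure ICC (Shrout-Fleiss ICC2),
    # ICC(C,1) the consistency form (ICC3), ICC(1,1) the one-way form
    label = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)",
             "ICC3": "ICC(C,1)"}.get(variant, variant)
    typed = table.set_index("Type")
    if label not in typed.index and variant in typed.index:
        label = variant
    icc = float(typed.loc[label, "ICC"])
    return AgreementResult(icc, icc_category(icc), float(slope),
                           float(intercept), variant)


# ---------------------------------------------------------------------------
# per-subject evaluation and cohort reports

def evaluate_masks(pred: SegMask, ref: SegMask) -> dict:
    """All per-subject metrics for one (prediction, reference) pair."""
    return {
        "subject_id": ref.subject_id,
        "timepoint": ref.timepoint,
        "dice_sat": dice3d(pred, ref, SAT),
        "dice_vat": dice3d(pred, ref, VAT),
        **dict(zip(("fp_pct", "fn_pct"), fp_fn_rates(pred, ref))),
        "sat_volume_mL": mask_volume(pred, SAT),
        "vat_volume_mL": mask_volume(pred, VAT),
        "ref_sat_volume_mL": mask_volume(ref, SAT),
        "ref_vat_volume_mL": mask_volume(ref, VAT),
    }


@dataclass
class MetricsReport:
    """Per-subject metric rows plus cohort-level summaries.

    Percentile convention for IQRs: linear interpolation.
    """

    per_subject: pd.DataFrame

    def __post_init__(self):
        pct = self.per_subject[["fp_pct", "fn_pct"]].to_numpy(float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("FP/FN percentages must lie in [0, 100]")

    def summary(self) -> pd.DataFrame:
        cols = ["dice_sat", "dice_vat", "fp_pct", "fn_pct",
                "sat_volume_mL", "vat_volume_mL"]
        rows = {}
        for c in cols:
            v = self.per_subject[c].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75],
                                        method="linear")
            rows[c] = {"median": med, "iqr_low": q1, "iqr_high": q3,
                       "min": v.min(), "max": v.max()}
        return pd.DataFrame(rows).T

    def volume_agreement(self, tissue: str, variant: str = "ICC2"
                         ) -> AgreementResult:
        pred = self.per_subject[f"{tissue}_volume_mL"]
        ref = self.per_subject[f"ref_{tissue}_volume_mL"]
        return icc_agreement(ref, pred, variant)


def delta_volume_analysis(report_t1: MetricsReport, report_t2: MetricsReport
                          ) -> pd.DataFrame:
    """Regression of predicted volume change on reference volume change.

    ΔVolume_AT = Volume2_AT - Volume1_AT per subject, for AT in
    {SAT, VAT}; returns one row per tissue with slope and intercept for
    the prediction-vs-reference delta regression.
    """
    t1 = report_t1.per_subject.set_index("subject_id")
    t2 = report_t2.per_subject.set_index("subject_id")
    unmatched = sorted(set(t1.index) ^ set(t2.index))
    if unmatched:
        raise ValueError(
            f"subjects missing one timepoint: {unmatched}"
        )
    t2 = t2.loc[t1.index]
    rows = []
    for tissue in ("sat", "vat"):
        d_pred = (t2[f"{tissue}_volume_mL"] - t1[f"{tissue}_volume_mL"]
                  ).to_numpy(float)
        d_ref = (t2[f"ref_{tissue}_volume_mL"] - t1[f"ref_{tissue}_volume_mL"]
                 ).to_numpy(float)
        if np.ptp(d_ref) > 0:
            slope, intercept = np.polyfit(d_ref, d_pred, 1)
            r = (np.corrcoef(d_ref, d_pred)[0, 1]
                 if np.ptp(d_pred) > 0 else np.nan)
        elif np.array_equal(d_ref, d_pred):
            slope, intercept, r = 1.0, 0.0, 1.0
        else:
            slope = intercept = r = np.nan
        rows.append({"tissue": tissue.upper(), "slope": float(slope),
                     "intercept": float(intercept), "r": float(r),
                     "n": len(d_ref)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics layer

def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p across >= 2 groups (tie-corrected ranks)."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Wilcoxon signed-rank p for paired series.

    Zero differences are discarded (classic Wilcoxon rule); if every
    difference is zero there is no evidence of a difference and p = 1.
    Exact distribution for n <= 25 without ties, normal approximation
    with tie correction otherwise (scipy's auto mode).
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if np.all(a == b):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.pvalue)


def benjamini_hochberg(p_values, q: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns (reject boolean array, adjusted p-values), in input order.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
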