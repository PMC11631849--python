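"""Cohort-level statistical validation of entropy tables.

A bundled 27-patient cohort table (substrate class, AF type, basal rhythm,
entropy computed on the original and on the resampled mesh, and one-year
recurrence) drives the validation layer: agreement between the two
entropy measurements (Bland-Altman), discrimination of abnormal substrate
(ROC / Youden), group comparisons (one-tailed two-sample t), and
inter-rater reproducibility (Cohen's kappa).

All operations here are deterministic; there is no randomness in this
module.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "PatientRecord",
    "BlandAltmanResult",
    "TTestResult",
    "RocResult",
    "load_fixture",
    "fixture_frame",
    "bland_altman",
    "one_tailed_t",
    "roc_auc",
    "cohens_kappa",
    "cohort_report",
]

_FIXTURE_SHA256 = "7ad03eedb6874f85e7dd73391515fe6e73e228b2099cc92e7a335b135671b746"

SUBSTRATES = ("normal", "abnormal")
AF_TYPES = ("paroxysmal", "persistent")
RHYTHMS = ("SR", "AF")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    substrate: str
    af_type: str
    basal_rhythm: str
    entropy_original: float
    lase: float
    recurrence: bool

    def validate(self) -> "PatientRecord":
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"bad substrate {self.substrate!r}")
        if self.af_type not in AF_TYPES:
            raise ValueError(f"bad af_type {self.af_type!r}")
        if self.basal_rhythm not in RHYTHMS:
            raise ValueError(f"bad basal_rhythm {self.basal_rhythm!r}")
        if not (np.isfinite(self.entropy_original) and np.isfinite(self.lase)):
            raise ValueError("non-finite entropy values")
        return self


def fixture_frame() -> pd.DataFrame:
    """The bundled cohort table as a DataFrame (checksum-guarded)."""
    ref = resources.files("lase").joinpath("data/table2.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"cohort fixture corrupted: sha256 {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixture() -> list[PatientRecord]:
    """All 27 patient records of the bundled cohort."""
    df = fixture_frame()
    return [
        PatientRecord(
            patient_id=int(r.patient_id),
            substrate=str(r.substrate),
            af_type=str(r.af_type),
            basal_rhythm=str(r.basal_rhythm),
            entropy_original=float(r.entropy_original),
            lase=float(r.lase),
            recurrence=str(r.recurrence).lower() == "yes",
        ).validate()
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int
    n_outside_loa: int
    n_within_band: int
    band: float


def bland_altman(a, b, band: float = 0.2) -> BlandAltmanResult:
    """Agreement between two paired measurement series.

    Differences ``d = a - b``; limits of agreement are
    ``mean(d) +/- 1.96 * sd(d)`` with the sample (n-1) standard
    deviation.  ``n_within_band`` counts differences within ``band`` of
    the mean difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        loa_low=lo,
        loa_high=hi,
        n=int(d.size),
        n_outside_loa=int(((d < lo) | (d > hi)).sum()),
        n_within_band=int((np.abs(d - mean) <= band).sum()),
        band=band,
    )


# ---------------------------------------------------------------------------
# t-test


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    df: float
    direction: str
    pooled: bool
    degenerate: bool = False


def one_tailed_t(group_a, group_b, direction: str = "greater", pooled: bool = True) -> TTestResult:
    """One-tailed two-sample t-test (pooled-variance Student by default).

    ``direction="greater"`` tests mean(a) > mean(b).  Set
    ``pooled=False`` for the Welch variant.  A fully degenerate input
    (zero variance in both groups, equal means) yields p = 0.5 by
    convention and is flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    df = a.size + b.size - 2 if pooled else np.nan
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 0.5, df, direction, pooled, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        p = 0.0 if (sign > 0) == (direction == "greater") else 1.0
        return TTestResult(sign * np.inf, p, df, direction, pooled, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=pooled, alternative=direction)
    df = float(res.df) if hasattr(res, "df") else df
    return TTestResult(float(res.statistic), float(res.pvalue), df, direction, pooled)


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    youden_cutoff: float
    sensitivity: float
    specificity: float
    positive_is_low: bool


def roc_auc(scores, labels, positive_is_low: bool = True) -> RocResult:
    """AUROC with a Youden-index cutoff.

    The AUC equals the Mann-Whitney U statistic normalized by
    ``n_pos * n_neg`` (ties count 1/2).  With ``positive_is_low`` (the
    entropy convention: disease = low score) a case is called positive
    when its score is at or below the threshold; the cutoff is reported
    on the original score scale, ties broken toward the more sensitive
    (lowest) threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    s = -scores if positive_is_low else scores
    u = sps.mannwhitneyu(s[labels], s[~labels], alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))

    thresholds = np.unique(scores)
    best = None
    for t in thresholds:
        if positive_is_low:
            pred = scores <= t
        else:
            pred = scores >= t
        sens = float((pred & labels).sum()) / len(pos)
        spec = float((~pred & ~labels).sum()) / len(neg)
        j = sens + spec - 1.0
        # tie-break toward the lowest threshold (more sensitive rule for
        # the low-score-positive orientation)
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t < best[1]):
            best = (j, float(t), sens, spec)
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        youden_cutoff=best[1],
        sensitivity=best[2],
        specificity=best[3],
        positive_is_low=positive_is_low,
    )


# ---------------------------------------------------------------------------
# kappa


def cohens_kappa(r1, r2) -> float:
    """Cohen's kappa between two label sequences.

    ``(p_o - p_e) / (1 - p_e)`` with the expected agreement from the
    marginals; perfect agreement returns 1 even when ``p_e = 1``.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.size == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    if np.array_equal(r1, r2):
        return 1.0
    return float(cohen_kappa_score(r1, r2))


# ---------------------------------------------------------------------------
# report


def _group_stats(values: np.ndarray, mask: np.ndarray) -> dict:
    sel = values[mask]
    return {
        "n": int(mask.sum()),
        "mean": float(sel.mean()) if len(sel) else np.nan,
        "sd": float(sel.std(ddof=1)) if len(sel) > 1 else np.nan,
    }


def cohort_report(records: list[PatientRecord], band: float = 0.2) -> dict:
    """Full cohort summary: counts, group stats, tests, ROC, agreement."""
    if not records:
        raise ValueError("empty cohort")
    lase = np.array([r.lase for r in records])
    orig = np.array([r.entropy_original for r in records])
    sub = np.array([r.substrate for r in records])
    af = np.array([r.af_type for r in records])
    rhythm = np.array([r.basal_rhythm for r in records])
    rec = np.array([r.recurrence for r in records])
    ids = np.array([r.patient_id for r in records])

    pa, pe = af == "paroxysmal", af == "persistent"
    nor, abn = sub == "normal", sub == "abnormal"
    sr, afr = rhythm == "SR", rhythm == "AF"

    report: dict = {
        "counts": {
            "patients": len(records),
            "paroxysmal": int(pa.sum()),
            "persistent": int(pe.sum()),
            "paroxysmal_normal_substrate": int((pa & nor).sum()),
            "normal_substrate": int(nor.sum()),
            "abnormal_substrate": int(abn.sum()),
            "sr_during_mapping": int(sr.sum()),
            "recurrence": int(rec.sum()),
        },
        "groups": {
            "lase_paroxysmal": _group_stats(lase, pa),
            "lase_persistent": _group_stats(lase, pe),
            "lase_normal": _group_stats(lase, nor),
            "lase_abnormal": _group_stats(lase, abn),
            "lase_sr": _group_stats(lase, sr),
            "lase_af_rhythm": _group_stats(lase, afr),
            "entropy_original_overall": _group_stats(orig, np.ones_like(pa)),
            "lase_overall": _group_stats(lase, np.ones_like(pa)),
        },
    }

    tests = {}
    for name, m1, m2 in (
        ("paroxysmal_vs_persistent", pa, pe),
        ("normal_vs_abnormal", nor, abn),
        ("sr_vs_af_rhythm", sr, afr),
    ):
        if m1.sum() >= 2 and m2.sum() >= 2:
            t = one_tailed_t(lase[m1], lase[m2], direction="greater")
            tests[name] = {"t": t.statistic, "p_one_tailed": t.p_value, "df": t.df}
    report["t_tests"] = tests

    if abn.any() and nor.any():
        roc = roc_auc(lase, abn, positive_is_low=True)
        report["roc_substrate"] = {
            "auc": roc.auc,
            "youden_cutoff": roc.youden_cutoff,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }

    ba = bland_altman(orig, lase, band=band)
    report["bland_altman_original_vs_lase"] = {
        "mean_difference": ba.mean_difference,
        "sd_difference": ba.sd_difference,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
        "n_outside_loa": ba.n_outside_loa,
        "n_within_band": ba.n_within_band,
        "band": ba.band,
    }

    order = np.argsort(lase, kind="stable")
    rank = np.empty(len(lase), dtype=int)
    rank[order] = np.arange(1, len(lase) + 1)
    report["recurrence"] = [
        {"patient_id": int(i), "lase": float(l), "lase_rank_ascending": int(k)}
        for i, l, k in zip(ids[rec], lase[rec], rank[rec])
    ]
    report["recurrence_in_lowest_two"] = int((rank[rec] <= 2).sum())
    report["recurrence_in_lowest_three"] = int((rank[rec] <= 3).sum())
    return report
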