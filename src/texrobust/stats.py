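"""Per-feature inter-reader robustness statistics and companion analyses.

The robustness of a radiomic feature against contouring variability is
summarised by two complementary quantities computed over a cohort of lesions
each segmented by two readers:

* the mean relative change ``MRC = mean_l |(RF_R1 - RF_R2) / RF_R1|``,
  reported in percent (individual relative changes are signed; the absolute
  value is applied at aggregation so the summary is nonnegative), and
* the intraclass correlation coefficient ICC(2,1): single-rater, two-way
  random-effects, absolute-agreement form.

A feature is flagged *robust* when ICC > 0.90 and MRC < 10% (strict
inequalities).  ICC values are banded as poor (<= 0.50), moderate
(0.50-0.75], good (0.75-0.90] and excellent (> 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, PairingError
from .features import GLRLM_FEATURES, TEXTURE_FEATURES, FeatureVector

ICC_ROBUST_THRESHOLD = 0.90
MRC_ROBUST_THRESHOLD_PCT = 10.0


@dataclass
class PairedFeatureTable:
    """Per-lesion feature values from two readers, aligned by lesion."""

    lesion_ids: list[str]
    reader1: pd.DataFrame        # rows = lesions, columns = features
    reader2: pd.DataFrame
    roi_mode: str = "3D"

    def __post_init__(self) -> None:
        if not (len(self.lesion_ids) == len(self.reader1) == len(self.reader2)):
            raise PairingError("lesion_ids and reader tables must align")
        if list(self.reader1.columns) != list(self.reader2.columns):
            raise PairingError("the two readers must share one feature roster")

    @classmethod
    def from_vectors(cls, reader1: list[FeatureVector],
                     reader2: list[FeatureVector],
                     roi_mode: str = "3D") -> "PairedFeatureTable":
        if len(reader1) != len(reader2):
            raise PairingError("paired feature lists differ in length")
        ids = [v.lesion_id or f"lesion{i:03d}" for i, v in enumerate(reader1)]
        df1 = pd.DataFrame([v.texture() for v in reader1], index=ids)
        df2 = pd.DataFrame([v.texture() for v in reader2], index=ids)
        return cls(lesion_ids=ids, reader1=df1, reader2=df2, roi_mode=roi_mode)

    @property
    def features(self) -> list[str]:
        return list(self.reader1.columns)

    def pairs(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        return (self.reader1[feature].to_numpy(dtype=float),
                self.reader2[feature].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# relative change / MRC
# ---------------------------------------------------------------------------

def relative_change(rf1: float, rf2: float) -> float:
    """Signed relative change (rf1 - rf2) / rf1 with R1 as the reference."""
    if rf1 == 0:
        raise DomainError("relative change is undefined for a zero reference")
    return (rf1 - rf2) / rf1


def _relative_changes(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-lesion signed relative changes; zero-reference or non-finite pairs
    are excluded.  Returns (valid changes, number excluded)."""
    valid = np.isfinite(x1) & np.isfinite(x2) & (x1 != 0)
    rc = (x1[valid] - x2[valid]) / x1[valid]
    return rc, int((~valid).sum())


def mean_relative_change(table: PairedFeatureTable) -> pd.DataFrame:
    """Per-feature MRC in percent, with the count of lesions used.

    MRC is the mean of the absolute signed relative changes; lesions with a
    zero R1 reference or non-finite values are excluded per feature and the
    exclusion count reported.
    """
    rows = {}
    for feat in table.features:
        rc, n_excluded = _relative_changes(*table.pairs(feat))
        mrc = float(np.mean(np.abs(rc)) * 100.0) if rc.size else np.nan
        rows[feat] = {"mrc_pct": mrc, "n_valid": rc.size,
                      "n_excluded": n_excluded}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

def icc_2_1_values(y1: np.ndarray, y2: np.ndarray,
                   form: str = "agreement") -> tuple[float, int]:
    """ICC for paired ratings from two raters, from the ANOVA mean squares.

    ``form="agreement"`` (default) is ICC(2,1): two-way random effects,
    absolute agreement, single rater::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    ``form="consistency"`` drops the rater-variance term from the
    denominator.  Returns ``(icc, n_valid)``; NaN when fewer than 3 complete
    pairs remain or the between-lesion variance is zero.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    valid = np.isfinite(y1) & np.isfinite(y2)
    y = np.column_stack([y1[valid], y2[valid]])
    n, k = y.shape
    if n < 3:
        return np.nan, n
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum()
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        return np.nan, n            # no between-lesion variance
    if form == "agreement":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif form == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise DomainError(f"unknown ICC form {form!r}")
    if denom == 0:
        return np.nan, n
    return float((ms_r - ms_e) / denom), n


def icc_2_1(table: PairedFeatureTable, feature: str,
            form: str = "agreement") -> tuple[float, int]:
    """ICC(2,1) of one feature between the two readers."""
    return icc_2_1_values(*table.pairs(feature), form=form)


def classify_icc(icc: float) -> str:
    """Agreement band: poor <= 0.50 < moderate <= 0.75 < good <= 0.90 < excellent."""
    if not np.isfinite(icc):
        return "undefined"
    if icc <= 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# robustness table and selection
# ---------------------------------------------------------------------------

def _family(feature: str) -> str:
    return "GLRLM" if feature in GLRLM_FEATURES else "GLCM"


def robustness_table(table: PairedFeatureTable,
                     icc_threshold: float = ICC_ROBUST_THRESHOLD,
                     mrc_threshold_pct: float = MRC_ROBUST_THRESHOLD_PCT,
                     icc_form: str = "agreement") -> pd.DataFrame:
    """Per-feature MRC, ICC, agreement band and robust flag for one ROI mode.

    ``robust`` requires *both* ICC strictly above ``icc_threshold`` and MRC
    strictly below ``mrc_threshold_pct``; features with an undefined MRC or
    ICC are never selectable.
    """
    mrc = mean_relative_change(table)
    rows = []
    for feat in table.features:
        icc, n_icc = icc_2_1(table, feat, form=icc_form)
        mrc_pct = mrc.loc[feat, "mrc_pct"]
        robust = (np.isfinite(icc) and np.isfinite(mrc_pct)
                  and icc > icc_threshold and mrc_pct < mrc_threshold_pct)
        rows.append({
            "feature": feat, "family": _family(feat),
            "mrc_pct": mrc_pct, "n_valid_mrc": int(mrc.loc[feat, "n_valid"]),
            "icc": icc, "n_valid_icc": n_icc,
            "band": classify_icc(icc), "robust": bool(robust),
        })
    return pd.DataFrame(rows).set_index("feature")


def select_robust(robtable: pd.DataFrame) -> list[str]:
    """Names of the features flagged robust in a robustness table."""
    return list(robtable.index[robtable["robust"]])


# ---------------------------------------------------------------------------
# companion statistics
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_x, paired_y) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied absolute differences get average
    ranks; the exact null distribution is used for n <= 25 untied samples,
    the normal approximation with continuity correction otherwise.  All
    differences zero leaves the test undefined (NaN statistic and p).
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if x.shape != y.shape:
        raise PairingError("paired samples differ in length")
    d = x - y
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return {"statistic": np.nan, "p_value": np.nan, "n": 0}
    untied = np.unique(np.abs(d)).size == n
    method = "exact" if (n <= 25 and untied) else "approx"
    res = sps.wilcoxon(d, correction=True, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(n)}


def spearman_rho(x, y) -> dict:
    """Spearman rank correlation with average ranks for ties (t-based p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise PairingError("samples differ in length")
    if x.size < 3:
        raise DomainError("Spearman correlation needs n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return {"rho": np.nan, "p_value": np.nan, "n": int(x.size)}
    res = sps.spearmanr(x, y)
    return {"rho": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(x.size)}


def evans_strength(rho: float) -> str:
    """Correlation-strength label for |rho| (Evans bands)."""
    if not np.isfinite(rho):
        return "undefined"
    a = abs(rho)
    if a < 0.20:
        return "very weak"
    if a < 0.40:
        return "weak"
    if a < 0.60:
        return "moderate"
    if a < 0.80:
        return "strong"
    return "very strong"


def size_agreement_analysis(size_params: dict[str, np.ndarray],
                            dice_values: np.ndarray,
                            hausdorff_values: np.ndarray) -> pd.DataFrame:
    """Association between lesion size and inter-reader agreement.

    For each size parameter (e.g. manual axial diameter, max 3D diameter,
    volume/area) against each similarity index, reports Spearman rho with
    its p-value, the ordinary least-squares slope/intercept and the Evans
    strength label.
    """
    indices = {"DC": np.asarray(dice_values, dtype=float),
               "HD": np.asarray(hausdorff_values, dtype=float)}
    rows = []
    for size_name, size_vals in size_params.items():
        size_vals = np.asarray(size_vals, dtype=float)
        for idx_name, idx_vals in indices.items():
            if size_vals.size != idx_vals.size:
                raise PairingError("size and similarity vectors must align")
            sp = spearman_rho(size_vals, idx_vals)
            if np.isfinite(sp["rho"]):
                fit = sps.linregress(size_vals, idx_vals)
                slope, intercept = float(fit.slope), float(fit.intercept)
            else:
                slope = intercept = np.nan
            rows.append({
                "size_parameter": size_name, "similarity_index": idx_name,
                "rho": sp["rho"], "p_value": sp["p_value"],
                "strength": evans_strength(sp["rho"]),
                "ols_slope": slope, "ols_intercept": intercept,
                "n": sp["n"],
            })
    return pd.DataFrame(rows)


def circular_roi_comparison(
    r1_manual: list[FeatureVector],
    enclosing: list[FeatureVector],
    inscribed: list[FeatureVector],
    r2_manual: list[FeatureVector],
) -> pd.DataFrame:
    """Inter-reader vs circular-ROI variability on the main lesions.

    For each feature, the MRC (and the signed mean relative change) of three
    comparisons, all with the R1 manual 2D values as the reference
    denominator: R1 vs R2 manual, R1 manual vs enclosing circle, R1 manual
    vs inscribed circle.  ``inter_reader_preponderant`` flags features whose
    inter-reader MRC is >= both circle-vs-manual MRCs, i.e. where switching
    to a simplified circular protocol would add no more variability than a
    second reader does.
    """
    if not (len(r1_manual) == len(enclosing) == len(inscribed) == len(r2_manual)):
        raise PairingError("all four feature lists must have the same length")

    def stack(vectors: list[FeatureVector]) -> pd.DataFrame:
        return pd.DataFrame([v.texture() for v in vectors])

    ref = stack(r1_manual)
    comparisons = {
        "inter_reader": stack(r2_manual),
        "enclosing": stack(enclosing),
        "inscribed": stack(inscribed),
    }
    rows = []
    for feat in TEXTURE_FEATURES:
        row: dict = {"feature": feat, "family": _family(feat)}
        for name, other in comparisons.items():
            rc, _ = _relative_changes(ref[feat].to_numpy(dtype=float),
                                      other[feat].to_numpy(dtype=float))
            row[f"mrc_{name}_pct"] = (float(np.mean(np.abs(rc)) * 100.0)
                                      if rc.size else np.nan)
            row[f"mean_rc_{name}_pct"] = (float(np.mean(rc) * 100.0)
                                          if rc.size else np.nan)
        ir = row["mrc_inter_reader_pct"]
        row["inter_reader_preponderant"] = bool(
            np.isfinite(ir)
            and np.isfinite(row["mrc_enclosing_pct"])
            and np.isfinite(row["mrc_inscribed_pct"])
            and ir >= row["mrc_enclosing_pct"]
            and ir >= row["mrc_inscribed_pct"]
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
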