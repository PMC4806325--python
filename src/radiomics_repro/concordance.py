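"""Test-retest concordance statistics.

Lin's concordance correlation coefficient (CCC) over subjects, Dixon's Q
outlier screening of per-subject paired differences, cut-off summary tables,
a paired-bootstrap CCC comparison, and heat-map export of the full
feature x setting-pair CCC matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features.registry import FeatureRegistry, load_registry
from .volume_io import STUDY_SETTINGS, ImagingSetting, THICKNESSES

DEFAULT_CUTOFFS = (0.85, 0.90, 0.95)


class ConcordanceError(ValueError):
    pass


# --------------------------------------------------------------------------
# Lin's CCC
# --------------------------------------------------------------------------

def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient with population variances.

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), using 1/n moment
    estimators as in Lin's original definition.  Pairs containing NaN are
    dropped first; fewer than 3 remaining pairs is an error.  Two identical
    constant vectors give 1 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ConcordanceError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ConcordanceError(f"need >= 3 complete pairs, have {n}")
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0  # identical constants
    return float(2.0 * sxy / denom)


# --------------------------------------------------------------------------
# Dixon's Q
# --------------------------------------------------------------------------

# Two-tailed critical values of Dixon's r10 ratio (Rorabacher 1991), n = 3..30.
_DIXON_Q_CRIT = {
    0.10: [0.941, 0.765, 0.642, 0.560, 0.507, 0.468, 0.437, 0.412, 0.392,
           0.376, 0.361, 0.349, 0.338, 0.329, 0.320, 0.313, 0.306, 0.300,
           0.295, 0.290, 0.285, 0.281, 0.277, 0.273, 0.269, 0.266, 0.263, 0.260],
    0.05: [0.970, 0.829, 0.710, 0.625, 0.568, 0.526, 0.493, 0.466, 0.444,
           0.426, 0.410, 0.396, 0.384, 0.374, 0.365, 0.356, 0.349, 0.342,
           0.337, 0.331, 0.326, 0.321, 0.317, 0.312, 0.308, 0.305, 0.301, 0.298],
    0.01: [0.994, 0.926, 0.821, 0.740, 0.680, 0.634, 0.598, 0.568, 0.542,
           0.522, 0.503, 0.488, 0.475, 0.463, 0.452, 0.442, 0.433, 0.425,
           0.418, 0.411, 0.404, 0.399, 0.393, 0.388, 0.384, 0.380, 0.376, 0.372],
}


@dataclass
class DixonResult:
    q: Optional[float]
    suspect_index: Optional[int]
    significant: Optional[bool]  # None = Not-Applicable (n > 30 or no spread)


def dixon_q(values: Sequence[float], alpha: float = 0.05) -> DixonResult:
    """Dixon's Q test for a single outlier in a small sample (3 <= n <= 30).

    Q is the gap between the suspect extreme (the extreme with the larger gap
    to its nearest neighbour) and that neighbour, divided by the range; it is
    compared two-sided against the standard critical-value table.  All-equal
    samples have no outlier; n > 30 returns a Not-Applicable flag.
    """
    vals = np.asarray(values, dtype=np.float64)
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n < 3:
        raise ConcordanceError(f"Dixon's Q needs n >= 3, have {n}")
    if alpha not in _DIXON_Q_CRIT:
        raise ConcordanceError(f"alpha must be one of {sorted(_DIXON_Q_CRIT)}")
    if n > 30:
        return DixonResult(q=None, suspect_index=None, significant=None)
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    rng = s[-1] - s[0]
    if rng == 0:
        return DixonResult(q=None, suspect_index=None, significant=False)
    gap_low = s[1] - s[0]
    gap_high = s[-1] - s[-2]
    if gap_high >= gap_low:
        q = gap_high / rng
        suspect = int(order[-1])
    else:
        q = gap_low / rng
        suspect = int(order[0])
    crit = _DIXON_Q_CRIT[alpha][n - 3]
    return DixonResult(q=float(q), suspect_index=suspect, significant=bool(q > crit))


# --------------------------------------------------------------------------
# setting-pair enumeration and the CCC matrix
# --------------------------------------------------------------------------

def identical_setting_pairs() -> List[str]:
    """The 6 identical-setting repeat-scan comparisons, in study order."""
    return [f"{s.label} vs {s.label}" for s in STUDY_SETTINGS]


def cross_kernel_pairs() -> List[str]:
    """The 3 equal-thickness sharp-vs-smooth comparisons."""
    return [f"{ImagingSetting(t, 'sharp').label} vs {ImagingSetting(t, 'smooth').label}"
            for t in THICKNESSES]


def all_pairs() -> List[str]:
    return identical_setting_pairs() + cross_kernel_pairs()


def _pair_settings(pair: str) -> Tuple[str, str]:
    try:
        left, right = (p.strip() for p in pair.split(" vs "))
        ImagingSetting.from_label(left)
        ImagingSetting.from_label(right)
    except ValueError as exc:
        raise ConcordanceError(f"unknown pair label {pair!r}") from exc
    if pair not in all_pairs():
        raise ConcordanceError(f"unknown pair label {pair!r}")
    return left, right


@dataclass
class CCCRecord:
    """CCC of one feature for one setting pair."""

    feature: str
    feature_class: str
    pair: str
    n: int
    ccc: float
    ccc_screened: Optional[float] = None
    n_screened: Optional[int] = None
    outliers: Tuple[str, ...] = ()


def _pivot(features: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "scan", "setting", "feature", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ConcordanceError(f"feature table missing columns {sorted(missing)}")
    # .pivot (not pivot_table) so NaN feature values survive
    return features.pivot(index="subject", columns=["scan", "setting"], values="value")


def ccc_matrix(features: pd.DataFrame,
               pairs: Optional[Iterable[str]] = None,
               outlier_policy: str = "none",
               alpha: float = 0.05,
               registry: Optional[FeatureRegistry] = None) -> List[CCCRecord]:
    """Per-feature CCCs for identical-setting and cross-kernel comparisons.

    ``features`` is the tidy extraction table (subject, scan, setting,
    feature, value).  Identical-setting pairs compare scan 1 against scan 2
    at the same setting; cross-kernel pairs compare scan 1 at the sharp (L)
    kernel against scan 2 at the smooth (S) kernel of equal thickness.

    With ``outlier_policy="dixon-screen"`` the per-subject paired differences
    of each feature are screened by Dixon's Q at ``alpha``; flagged subjects
    are removed and the screened CCC is reported alongside the raw one.
    """
    if outlier_policy not in ("none", "dixon-screen"):
        raise ConcordanceError(f"unknown outlier policy {outlier_policy!r}")
    registry = registry or load_registry()
    pair_labels = list(pairs) if pairs is not None else all_pairs()
    for p in pair_labels:
        _pair_settings(p)

    records: List[CCCRecord] = []
    for feature_name in registry.names:
        sub = features[features["feature"] == feature_name]
        wide = _pivot(sub)
        for pair in pair_labels:
            left, right = _pair_settings(pair)
            try:
                x = wide[(1, left)].to_numpy(dtype=float)
                y = wide[(2, right)].to_numpy(dtype=float)
            except KeyError as exc:
                raise ConcordanceError(f"feature table lacks data for {pair}: {exc}")
            subjects = wide.index.to_numpy()
            keep = ~(np.isnan(x) | np.isnan(y))
            rec = CCCRecord(
                feature=feature_name,
                feature_class=registry.class_of(feature_name),
                pair=pair,
                n=int(keep.sum()),
                ccc=lin_ccc(x, y) if keep.sum() >= 3 else float("nan"),
            )
            if outlier_policy == "dixon-screen" and keep.sum() >= 3 and keep.sum() <= 30:
                diffs = (x - y)[keep]
                res = dixon_q(diffs, alpha=alpha)
                if res.significant:
                    kept_subjects = subjects[keep]
                    drop = kept_subjects[res.suspect_index]
                    sel = kept_subjects != drop
                    if sel.sum() >= 3:
                        rec.ccc_screened = lin_ccc(x[keep][sel], y[keep][sel])
                        rec.n_screened = int(sel.sum())
                        rec.outliers = (str(drop),)
                else:
                    rec.ccc_screened = rec.ccc
                    rec.n_screened = rec.n
            records.append(rec)
    return records


def records_to_frame(records: List[CCCRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature, "class": r.feature_class, "pair": r.pair,
        "n": r.n, "ccc": r.ccc, "ccc_screened": r.ccc_screened,
        "n_screened": r.n_screened, "outliers": ";".join(r.outliers),
    } for r in records])


# --------------------------------------------------------------------------
# cut-off summary (Table-1 style)
# --------------------------------------------------------------------------

def summarize_cutoffs(records: List[CCCRecord],
                      cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                      use_screened: bool = False,
                      registry: Optional[FeatureRegistry] = None) -> pd.DataFrame:
    """Count (and percentage of 89) of features with CCC >= cut-off, per pair.

    Not-Available CCCs count as non-reproducible.  Requires every registry
    feature to be present for each pair.  Percentages are rounded to integers.
    """
    registry = registry or load_registry()
    frame = records_to_frame(records)
    if use_screened:
        frame["ccc"] = frame["ccc_screened"].fillna(frame["ccc"])
    rows = []
    for pair in dict.fromkeys(frame["pair"]):
        sub = frame[frame["pair"] == pair]
        missing = set(registry.names) - set(sub["feature"])
        if missing:
            raise ConcordanceError(
                f"pair {pair!r} missing features: {sorted(missing)[:5]}"
                f"{'...' if len(missing) > 5 else ''}")
        row: Dict[str, object] = {"pair": pair}
        for cut in sorted(cutoffs):
            count = int((sub["ccc"] >= cut).sum())  # NaN compares False
            row[f"count_{cut:g}"] = count
            row[f"pct_{cut:g}"] = int(round(100.0 * count / len(registry)))
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# paired-bootstrap CCC comparison
# --------------------------------------------------------------------------

def compare_ccc(x_a: Sequence[float], y_a: Sequence[float],
                x_b: Sequence[float], y_b: Sequence[float],
                n_boot: int = 2000, seed: int = 0) -> float:
    """Two-sided p-value for a difference between two CCCs on the same subjects.

    Resamples subjects with replacement (paired across both feature variants),
    recomputes both CCCs per resample, and returns the percentile two-sided p
    for delta = ccc_a - ccc_b != 0.  Deterministic given ``seed``.
    """
    x_a, y_a, x_b, y_b = (np.asarray(v, dtype=np.float64) for v in (x_a, y_a, x_b, y_b))
    n = len(x_a)
    if not (len(y_a) == len(x_b) == len(y_b) == n):
        raise ConcordanceError("all four vectors must cover the same subjects")
    if n < 5:
        raise ConcordanceError("need at least 5 subjects")
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            deltas[b] = lin_ccc(x_a[idx], y_a[idx]) - lin_ccc(x_b[idx], y_b[idx])
        except ConcordanceError:
            deltas[b] = np.nan
    deltas = deltas[~np.isnan(deltas)]
    if len(deltas) == 0:
        return float("nan")
    p_low = float(np.mean(deltas <= 0.0))
    p_high = float(np.mean(deltas >= 0.0))
    return float(min(1.0, 2.0 * min(p_low, p_high)))


# --------------------------------------------------------------------------
# heat-map export
# --------------------------------------------------------------------------

def heatmap_frame(records: List[CCCRecord],
                  registry: Optional[FeatureRegistry] = None,
                  use_screened: bool = False) -> pd.DataFrame:
    """89 x 9 CCC matrix: registry-ordered features x study setting pairs.

    Missing (Not-Available) values stay as NaN and serialize to empty CSV
    cells, never zero.
    """
    registry = registry or load_registry()
    frame = records_to_frame(records)
    value_col = "ccc_screened" if use_screened else "ccc"
    if use_screened:
        frame[value_col] = frame["ccc_screened"].fillna(frame["ccc"])
    cols = [p for p in all_pairs() if p in set(frame["pair"])]
    out = pd.DataFrame(index=registry.names, columns=cols, dtype=float)
    for r in frame.itertuples(index=False):
        if r.pair in cols:
            out.loc[r.feature, r.pair] = getattr(r, value_col) if use_screened else r.ccc
    out.index.name = "feature"
    return out


def export_heatmap(records: List[CCCRecord], csv_path: Path | str,
                   figure_path: Optional[Path | str] = None,
                   registry: Optional[FeatureRegistry] = None) -> pd.DataFrame:
    """Write the CCC matrix CSV and (optionally) a monotone-red heat-map figure."""
    registry = registry or load_registry()
    matrix = heatmap_frame(records, registry=registry)
    matrix.to_csv(csv_path, float_format="%.10g")
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 14))
        data = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
        im = ax.imshow(data, cmap="Reds", vmin=0.0, vmax=1.0, aspect="auto")
        ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=4)
        fig.colorbar(im, ax=ax, label="CCC")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return matrix
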