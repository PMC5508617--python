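"""Reproducibility- and redundancy-driven feature selection.

Radiomic features are kept only if they are (1) reproducible across
test-retest acquisitions, (2) informative relative to replicate noise, and
(3) not redundant with an already-kept feature:

* CCC — Lin's concordance correlation coefficient between test and retest
  values; threshold 0.9.
* DR — "dynamic range": one minus the mean absolute test-retest difference
  normalized by the total observed value range; threshold 0.9.  Near 1
  means replicate noise is small relative to inter-subject spread.
* R^2 pruning — features are ranked by DR (descending) and accepted
  greedily iff their squared Pearson correlation with every already-accepted
  feature stays below ``r2_max`` (default 0.95).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionReport",
    "ccc",
    "dynamic_range",
    "redundancy_prune",
    "select_features",
    "retest_feature_frames",
]

DEFAULT_CCC_MIN = 0.9
DEFAULT_DR_MIN = 0.9
DEFAULT_R2_MAX = 0.95


@dataclasses.dataclass
class SelectionReport:
    """Per-feature reproducibility statistics and the surviving feature list."""

    ccc: "pd.Series"
    dr: "pd.Series"
    reproducible: list[str]  # passed CCC and DR thresholds
    selected: list[str]  # after redundancy pruning
    ccc_min: float = DEFAULT_CCC_MIN
    dr_min: float = DEFAULT_DR_MIN
    r2_max: float = DEFAULT_R2_MAX

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "ccc_min": self.ccc_min,
                "dr_min": self.dr_min,
                "r2_max": self.r2_max,
            },
            "n_reproducible": len(self.reproducible),
            "n_selected": len(self.selected),
            "selected": self.selected,
            "ccc": {k: float(v) for k, v in self.ccc.items()},
            "dr": {k: float(v) for k, v in self.dr.items()},
        }


def _paired(test, retest) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(test, dtype=float)
    y = np.asarray(retest, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("test/retest must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValidationError(f"need >= 3 paired subjects, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in test/retest data")
    return x, y


def ccc(test, retest) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``; two constant
    sequences carry no concordance information and return 0.
    """
    x, y = _paired(test, retest)
    vx = x.var()
    vy = y.var()
    dm = x.mean() - y.mean()
    denom = vx + vy + dm * dm
    if denom == 0.0:
        logger.warning("CCC undefined for two identical constant sequences; returning 0")
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


def dynamic_range(test, retest) -> float:
    """DR = 1 - mean|test - retest| / (overall max - overall min), in [0, 1]."""
    x, y = _paired(test, retest)
    both = np.concatenate([x, y])
    span = both.max() - both.min()
    if span == 0.0:
        logger.warning("zero inter-subject range; DR set to 0")
        return 0.0
    dr = 1.0 - np.abs(x - y).mean() / span
    return float(np.clip(dr, 0.0, 1.0))


def redundancy_prune(
    table: FeatureTable,
    kept: list[str],
    r2_max: float = DEFAULT_R2_MAX,
    ranking: "pd.Series | None" = None,
) -> list[str]:
    """Greedy de-correlation of candidate features.

    Candidates are visited in ``ranking`` order (DR descending when called
    from :func:`select_features`; input order if no ranking is given) and
    accepted iff their pairwise Pearson R^2 with every already-accepted
    feature is below ``r2_max``.  Deterministic given inputs.
    """
    if len(kept) < 2:
        return list(kept)
    if len(table) < 4:
        raise ValidationError(f"need >= 4 subjects for redundancy pruning, got {len(table)}")
    if ranking is not None:
        order = sorted(kept, key=lambda f: (-float(ranking[f]), kept.index(f)))
    else:
        order = list(kept)
    data = table.features()[order].to_numpy(dtype=float)
    # correlation with constant columns is undefined -> treat as fully redundant
    sd = data.std(axis=0)
    accepted: list[int] = []
    names: list[str] = []
    for j, name in enumerate(order):
        if sd[j] == 0.0:
            continue
        ok = True
        for a in accepted:
            r = np.corrcoef(data[:, j], data[:, a])[0, 1]
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(j)
            names.append(name)
    return names


def retest_feature_frames(
    vectors_test, vectors_retest
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Align two lists of FeatureVectors into (subjects x features) frames."""
    t = pd.DataFrame([v.values for v in vectors_test], index=[v.subject_id for v in vectors_test])
    r = pd.DataFrame(
        [v.values for v in vectors_retest], index=[v.subject_id for v in vectors_retest]
    )
    if list(t.index) != list(r.index) or list(t.columns) != list(r.columns):
        raise ValidationError("test and retest feature sets are not aligned")
    return t, r


def select_features(
    cohort_table: FeatureTable,
    test_frame: "pd.DataFrame",
    retest_frame: "pd.DataFrame",
    ccc_min: float = DEFAULT_CCC_MIN,
    dr_min: float = DEFAULT_DR_MIN,
    r2_max: float = DEFAULT_R2_MAX,
) -> SelectionReport:
    """Full selection pass: CCC filter, then DR filter, then R^2 pruning.

    ``test_frame``/``retest_frame`` are aligned (subjects x features) frames
    from the paired reproducibility scans; redundancy is assessed on the
    training cohort.  An empty survivor set is a legal result.
    """
    if len(test_frame) < 3:
        raise ValidationError("retest pairs must cover >= 3 subjects")
    names = [f for f in cohort_table.feature_names if f in test_frame.columns]
    ccc_s = pd.Series(
        {f: ccc(test_frame[f].to_numpy(), retest_frame[f].to_numpy()) for f in names}
    )
    dr_s = pd.Series(
        {f: dynamic_range(test_frame[f].to_numpy(), retest_frame[f].to_numpy()) for f in names}
    )
    reproducible = [f for f in names if ccc_s[f] >= ccc_min and dr_s[f] >= dr_min]
    if not reproducible:
        logger.warning("no feature passed the CCC/DR reproducibility filters")
        selected: list[str] = []
    else:
        training = cohort_table.cohort("training")
        if len(training) == 0:
            training = cohort_table
        selected = redundancy_prune(training, reproducible, r2_max=r2_max, ranking=dr_s)
    return SelectionReport(
        ccc=ccc_s,
        dr=dr_s,
        reproducible=reproducible,
        selected=selected,
        ccc_min=ccc_min,
        dr_min=dr_min,
        r2_max=r2_max,
    )
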