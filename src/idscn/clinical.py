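"""Clinical statistics: total CSVD MRI burden, demographic group tests,
and Spearman correlations between network edges / burden and depression
scores.

The total MRI burden of cerebral small vessel disease counts one point
for each of four markers present — lacunes, cerebral microbleeds (CMBs),
white matter hyperintensities (WMHs) and enlarged perivascular spaces
(EPVS) — for a 0-4 ordinal score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerProfile",
    "MarkerThresholds",
    "BurdenScore",
    "total_csvd_burden",
    "burden_table",
    "two_sample_t_from_summary",
    "two_sample_t",
    "chi_square_2x2",
    "spearman_with_bonferroni",
]

MARKERS = ("lacune", "cmb", "wmh", "epvs")


@dataclass(frozen=True)
class MarkerThresholds:
    """Cut-offs for binarizing marker counts/volumes into presence.

    Defaults treat any occurrence as present (>= 1 lacune, >= 1 CMB,
    any positive WMH volume, >= 1 EPVS).
    """

    lacune_count: int = 1
    cmb_count: int = 1
    wmh_volume_ml: float = 0.0   # present if volume strictly greater
    epvs_count: int = 1


@dataclass(frozen=True)
class MarkerProfile:
    """Per-patient marker quantities; booleans are accepted directly,
    numeric quantities are binarized with the configured thresholds."""

    lacune: float | bool
    cmb: float | bool
    wmh: float | bool
    epvs: float | bool
    thresholds: MarkerThresholds = MarkerThresholds()

    def presence(self) -> dict[str, bool]:
        th = self.thresholds
        def _present(value, cut, strict):
            if isinstance(value, (bool, np.bool_)):
                return bool(value)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError("marker value missing")
            if value < 0:
                raise ValueError("marker counts/volumes must be >= 0")
            return value > cut if strict else value >= cut
        return {
            "lacune": _present(self.lacune, th.lacune_count, strict=False),
            "cmb": _present(self.cmb, th.cmb_count, strict=False),
            "wmh": _present(self.wmh, th.wmh_volume_ml, strict=True),
            "epvs": _present(self.epvs, th.epvs_count, strict=False),
        }


@dataclass(frozen=True)
class BurdenScore:
    subject_id: str
    score: int
    contributions: dict[str, bool]

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 4:
            raise ValueError("burden score must lie in 0..4")


def total_csvd_burden(profile: MarkerProfile, subject_id: str = "") -> BurdenScore:
    """One point per present marker; maximum 4."""
    presence = profile.presence()
    return BurdenScore(
        subject_id=subject_id,
        score=int(sum(presence.values())),
        contributions=presence,
    )


def burden_table(clinical: pd.DataFrame,
                 thresholds: MarkerThresholds = MarkerThresholds()) -> pd.DataFrame:
    """Burden scores for a clinical table with *_present (or raw count)
    columns; returns subject_id-indexed scores plus contributions."""
    rows = {}
    for sid, row in clinical.iterrows():
        values = {}
        for m in MARKERS:
            if f"{m}_present" in row.index:
                values[m] = bool(row[f"{m}_present"])
            elif m in row.index:
                values[m] = float(row[m])
            else:
                raise ValueError(f"clinical table lacks marker column for {m!r}")
        score = total_csvd_burden(MarkerProfile(**values, thresholds=thresholds),
                                  subject_id=str(sid))
        rows[sid] = {"burden": score.score,
                     **{f"{m}_present": int(v)
                        for m, v in score.contributions.items()}}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")


# ---------------------------------------------------------------------------
# two-sample tests

def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Unpaired two-sample t-test from summary statistics.

    Returns (t, df, two-sided p). ``variant`` is "pooled" (Student) or
    "welch" (Satterthwaite df).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def two_sample_t(x: Sequence[float], y: Sequence[float],
                 variant: str = "pooled") -> tuple[float, float, float]:
    """Raw-data counterpart of :func:`two_sample_t_from_summary`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y),
        variant=variant,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default (matching SPSS's "Pearson
    Chi-Square" line). All margins must be positive.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("cell counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    assert df == 1
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# correlation analyses

def spearman_with_bonferroni(
    pairs: Sequence[tuple[Sequence[float], Sequence[float], str]],
    *,
    alpha: float = 0.05,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Spearman rank correlations (average-rank ties) for several (x, y)
    pairs, with a shared corrected significance threshold.

    By default the threshold is alpha / n_pairs (Bonferroni). A fixed
    ``threshold`` (e.g. the 0.005 used in the source protocol for two
    tests) may be supplied instead; a mismatch with alpha / n_pairs is
    logged, not silently adopted.
    """
    n_tests = len(pairs)
    if n_tests == 0:
        raise ValueError("no correlation pairs given")
    bonf = alpha / n_tests
    if threshold is None:
        threshold = bonf
    elif not np.isclose(threshold, bonf):
        logger.info(
            "using configured Spearman threshold %.4g (Bonferroni alpha/m "
            "would be %.4g)", threshold, bonf,
        )
    rows = []
    for x, y, label in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 4:
            raise ValueError(f"pair {label!r}: need >= 4 paired observations")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(
                f"pair {label!r}: constant input, Spearman rho undefined"
            )
        res = stats.spearmanr(x, y)
        rows.append({
            "label": label,
            "rho": float(res.statistic),
            "p": float(res.pvalue),
            "n": len(x),
            "threshold": threshold,
            "significant": bool(res.pvalue < threshold),
        })
    return pd.DataFrame(rows)
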