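"""Statistical comparisons and ancillary quantifications.

Two-group comparisons follow the conventions of the wound-healing and
calcium-wave literature: classical equal-variance two-sample t test for
approximately normal quantities (cell areas, healing times and speeds),
Mann-Whitney U for skewed counts and areas (wave sizes), significance at
alpha = 0.05, and mean +/- SEM summaries.  Also provided: per-cell area
morphometry from a labeled segmentation mask and the 2^-ddCt fold change
for quantitative PCR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    test: str  # "t_unpaired" | "mann_whitney"
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        """Significance at the conventional alpha = 0.05."""
        return self.p_value < 0.05


def mean_sem(sample) -> tuple[float, float]:
    """Mean and standard error of the mean (sd with ddof=1 over sqrt(n)).

    With a single observation the SEM is undefined and returned as NaN.
    """
    v = np.asarray(sample, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def t_test_unpaired(
    sample_a,
    sample_b,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> ComparisonResult:
    """Two-sample unpaired Student's t test (two-sided).

    Classical equal-variance by default; ``welch=True`` drops the equal
    variance assumption.  Degenerate inputs with zero pooled variance give
    p = 1 when the means agree and are rejected otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    ma, sa = mean_sem(a)
    mb, sb = mean_sem(b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if ma == mb:
            stat, p = 0.0, 1.0
        else:
            raise ValueError(
                "degenerate comparison: zero variance with unequal means"
            )
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(
        labels[0], labels[1], a.size, b.size, ma, sa, mb, sb,
        "t_unpaired", float(stat), float(p),
    )


def mann_whitney(
    sample_a, sample_b, labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when n_a + n_b <= 20 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction.  Identical samples (all ties) give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
    if math.isnan(p):  # zero-variance rank distribution (all values tied)
        p = 1.0
    ma, sa = mean_sem(a)
    mb, sb = mean_sem(b)
    return ComparisonResult(
        labels[0], labels[1], a.size, b.size, ma, sa, mb, sb,
        "mann_whitney", float(stat), float(min(p, 1.0)),
    )


def compare_auto(sample_a, sample_b, metric: str, labels=("a", "b")):
    """Pick the conventional test for a metric family.

    Wave cell counts and wave areas -> Mann-Whitney; cell areas, healing
    time/speed and other approximately normal metrics -> Student's t.
    """
    nonparametric = any(k in metric.lower() for k in ("wave", "count"))
    fn = mann_whitney if nonparametric else t_test_unpaired
    return fn(sample_a, sample_b, labels=labels)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all reports;
    raw p-values at alpha = 0.05 are the package's reporting convention)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def comparison_frame(results, holm: bool = False) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "group_a": r.group_a, "group_b": r.group_b,
                "test": r.test, "n_a": r.n_a, "n_b": r.n_b,
                "mean_a": r.mean_a, "sem_a": r.sem_a,
                "mean_b": r.mean_b, "sem_b": r.sem_b,
                "statistic": r.statistic, "p": r.p_value,
                "significant": r.significant,
            }
        )
    frame = pd.DataFrame(rows)
    if holm and len(frame):
        frame["p_holm"] = holm_adjust(frame["p"].to_numpy())
        frame["significant_holm"] = frame["p_holm"] < 0.05
    return frame


def cell_areas(label_mask: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Per-cell areas from an integer label mask (0 = background).

    Returns a table of (label_id, area_px, area_um2) with
    ``area_um2 = area_px * pixel_size_um**2``.
    """
    mask = np.asarray(label_mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must be integer-valued")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    ids, counts = np.unique(mask[mask > 0], return_counts=True)
    if ids.size == 0:
        warnings.warn("label mask contains no cells", stacklevel=2)
    return pd.DataFrame(
        {
            "label_id": ids.astype(int),
            "area_px": counts.astype(int),
            "area_um2": counts * pixel_size_um**2,
        }
    )


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each of the sample and the
    calibrator; the fold change is 2^-(dCt_sample - dCt_calibrator), so a
    sample identical to its calibrator has fold change 1.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator,
           ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))
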