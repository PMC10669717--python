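"""Validation arithmetic for the case-control expression study.

Three pieces:

* relative gene expression by the 2^-ddCt method, normalized to a
  housekeeping reference gene (GAPDH in the study) and a calibrator group
  (healthy controls by default);
* one-way ANOVA across the study groups with Tukey's HSD post-hoc test
  (studentized-range adjusted pairwise p-values, Tukey–Kramer form for
  unequal group sizes);
* ELISA standard-curve quantification — linear or four-parameter-logistic
  (4PL) calibration and inverse interpolation of sample absorbances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CtMeasurement",
    "FoldChangeResult",
    "GroupComparison",
    "TukeyPair",
    "ElisaCurve",
    "STUDY_GROUPS",
    "delta_delta_ct",
    "one_way_anova",
    "tukey_hsd",
    "group_comparison",
    "fit_standard_curve",
    "interpolate",
    "read_ct_table",
    "read_elisa_csv",
]

STUDY_GROUPS = ("untreated_T2DM", "metformin", "glimepiride", "healthy_control")


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR cycle-threshold reading."""

    sample_id: str
    group: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self):
        if not (0 < self.ct < 45):
            raise ValueError(f"Ct {self.ct} outside (0, 45)")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-sample relative expression: dCt, ddCt and fold = 2^-ddCt."""

    sample_id: str
    group: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float  # mean_a - mean_b
    q: float
    p_adjusted: float


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey HSD for one gene or analyte."""

    analyte: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    F: float
    p_anova: float
    tukey: list[TukeyPair]


@dataclass
class ElisaCurve:
    """Fitted ELISA standard curve.

    ``model`` is "linear" (absorbance = a + b*conc, least squares) or
    "4pl" (absorbance = d + (a - d) / (1 + (conc/c)^b)).  The quantifiable
    range is the absorbance span of the standards; readings outside it are
    flagged out-of-range rather than extrapolated.
    """

    standards: list[tuple[float, float]]
    model: str
    params: tuple[float, ...]
    response_range: tuple[float, float]


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------

def delta_delta_ct(
    data: Iterable[CtMeasurement],
    reference_gene: str = "GAPDH",
    calibrator_group: str = "healthy_control",
) -> list[FoldChangeResult]:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged to one Ct per (sample, gene); then
    per sample dCt = Ct_gene - Ct_reference, ddCt = dCt - mean(dCt over
    the calibrator group), fold = 2^-ddCt.  Samples missing the reference
    gene are excluded with a warning; an empty calibrator group is an
    error.
    """
    df = pd.DataFrame(
        [(m.sample_id, m.group, m.gene.upper(), m.ct) for m in data],
        columns=["sample_id", "group", "gene", "ct"],
    )
    if df.empty:
        raise ValueError("no Ct measurements")
    ref = reference_gene.upper()
    ct = (
        df.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref_ct = ct[ct.gene == ref].set_index("sample_id")["ct"]
    missing = set(ct.sample_id) - set(ref_ct.index)
    if missing:
        warnings.warn(
            f"{len(missing)} sample(s) missing reference gene {ref}: excluded"
        )
        ct = ct[~ct.sample_id.isin(missing)]
    genes = ct[ct.gene != ref].copy()
    genes["delta_ct"] = genes.ct - genes.sample_id.map(ref_ct)
    results: list[FoldChangeResult] = []
    for gene, sub in genes.groupby("gene", sort=True):
        calib = sub[sub.group == calibrator_group]
        if calib.empty:
            raise ValueError(
                f"calibrator group {calibrator_group!r} empty for gene {gene}"
            )
        baseline = calib.delta_ct.mean()
        for row in sub.itertuples():
            ddct = row.delta_ct - baseline
            results.append(
                FoldChangeResult(
                    row.sample_id, row.group, gene,
                    float(row.delta_ct), float(ddct), float(2.0 ** -ddct),
                )
            )
    return results


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def _validated_groups(values_by_group: Mapping[str, Sequence[float]]):
    if len(values_by_group) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        arrays[g] = arr
    return arrays


def one_way_anova(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns (F, p) with df (G-1, sum(n_g) - G); p is the upper tail of the
    F distribution.  Computed from between/within sums of squares rather
    than delegated, so the F statistic is available exactly as defined.
    """
    arrays = _validated_groups(values_by_group)
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    if ss_within == 0:
        # degenerate: no within-group variance
        return (float("inf"), 0.0) if ss_between > 0 else (0.0, 1.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def tukey_hsd(values_by_group: Mapping[str, Sequence[float]]) -> list[TukeyPair]:
    """Tukey's HSD all-pairs post-hoc test.

    For each pair, q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))
    (the Tukey–Kramer statistic, reducing to classical Tukey at equal n);
    the adjusted p is the studentized-range upper tail with parameters
    (G, sum(n_g) - G).
    """
    arrays = _validated_groups(values_by_group)
    k = len(arrays)
    df_w = sum(a.size for a in arrays.values()) - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    pairs = []
    for (ga, a), (gb, b) in combinations(arrays.items(), 2):
        diff = a.mean() - b.mean()
        if msw == 0:
            q = float("inf") if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p = float(np.clip(stats.studentized_range.sf(q, k, df_w), 0.0, 1.0))
        pairs.append(TukeyPair(ga, gb, float(diff), float(q), p))
    return pairs


def group_comparison(
    analyte: str, values_by_group: Mapping[str, Sequence[float]]
) -> GroupComparison:
    """Bundle means ± SD, ANOVA and Tukey HSD for one gene or analyte."""
    arrays = _validated_groups(values_by_group)
    F, p = one_way_anova(values_by_group)
    return GroupComparison(
        analyte=analyte,
        group_means={g: float(a.mean()) for g, a in arrays.items()},
        group_sds={g: float(a.std(ddof=1)) for g, a in arrays.items()},
        group_ns={g: int(a.size) for g, a in arrays.items()},
        F=F,
        p_anova=p,
        tukey=tukey_hsd(values_by_group),
    )


# ---------------------------------------------------------------------------
# ELISA standard curve
# ---------------------------------------------------------------------------

def _four_pl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_standard_curve(
    standards: Sequence[tuple[float, float]], model: str = "linear"
) -> ElisaCurve:
    """Fit the calibration model to (concentration ng/mL, absorbance) pairs.

    Linear: ordinary least squares.  4PL: iterative least squares started
    from a = min absorbance, d = max absorbance, c = median positive
    concentration, b = 1.
    """
    concs = np.array([s[0] for s in standards], dtype=float)
    absorb = np.array([s[1] for s in standards], dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(np.diff(concs) <= 0):
        raise ValueError("standard concentrations must be strictly increasing")
    if model == "linear":
        if len(standards) < 2:
            raise ValueError("linear curve needs >= 2 standards")
        b, a = np.polyfit(concs, absorb, 1)  # absorbance = a + b*conc
        params = (float(a), float(b))
    elif model == "4pl":
        if len(standards) < 4:
            raise ValueError("4PL curve needs >= 4 standards")
        p0 = (
            float(absorb.min()),
            1.0,
            float(np.median(concs[concs > 0])),
            float(absorb.max()),
        )
        popt, _ = optimize.curve_fit(_four_pl, concs, absorb, p0=p0, maxfev=20000)
        params = tuple(float(v) for v in popt)
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = (float(absorb.min()), float(absorb.max()))
    return ElisaCurve(list(standards), model, params, rng)


def interpolate(
    curve: ElisaCurve, absorbance: float, allow_extrapolation: bool = False
) -> tuple[float | None, bool]:
    """Invert the fitted curve: absorbance -> concentration ng/mL.

    Returns ``(concentration, in_range)``.  Readings outside the response
    span of the standards are flagged and yield ``None`` unless
    ``allow_extrapolation`` is set.
    """
    lo, hi = curve.response_range
    in_range = lo <= absorbance <= hi
    if not in_range and not allow_extrapolation:
        return None, False
    if curve.model == "linear":
        a, b = curve.params
        if b == 0:
            raise ZeroDivisionError("flat standard curve")
        return (absorbance - a) / b, in_range
    a, b, c, d = curve.params
    ratio = (a - d) / (absorbance - d) - 1.0
    if ratio <= 0:
        return None, False
    return c * ratio ** (1.0 / b), in_range


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Read a Ct CSV with columns sample_id,group,gene,replicate,ct."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "gene", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        CtMeasurement(str(r.sample_id), str(r.group), str(r.gene),
                      int(r.replicate), float(r.ct))
        for r in df.itertuples()
    ]


def read_elisa_csv(path: str | Path):
    """Read an ELISA CSV with a standards block and a samples block.

    Columns: kind,id,group,concentration,absorbance — kind is "standard"
    (concentration filled) or "sample" (group filled).  Returns
    (standards, samples) where standards is a list of (conc, absorbance)
    and samples a DataFrame of id/group/absorbance.
    """
    df = pd.read_csv(path)
    std = df[df["kind"] == "standard"].sort_values("concentration")
    standards = list(zip(std["concentration"].astype(float), std["absorbance"].astype(float)))
    samples = df[df["kind"] == "sample"][["id", "group", "absorbance"]].reset_index(drop=True)
    return standards, samples
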