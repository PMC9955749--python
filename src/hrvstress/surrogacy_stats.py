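"""Surrogate-validity statistics for ultra-short-term HRV features.

An ultra-short-term feature (30 s ... 3 min) is a *valid surrogate* of its
5-minute counterpart when

(a) its low-vs-high stress contrast is significant at the ultra-short scale
    with the same direction as at 5 min (also significant there), and
(b) it correlates strongly with the paired 5-minute value — Spearman
    rho > 0.7 with p < 0.05 — within BOTH stress levels separately.

Pairing is structural: every ultra-short epoch shares the midpoint of its
parent 5-minute epoch, so agreement is assessed on (record, parent) pairs.
Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD of paired
differences) complement the rank correlation with an absolute-agreement
view.

The stress contrast is a two-sided pooled-variance Student's t-test per
feature and scale, with epochs pooled across records as independent
observations (a Welch option exists behind a flag).  No multiple-testing
correction is applied to the per-feature p-values; a Holm-adjusted column
is emitted alongside as supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hrv_features import FEATURE_NAMES
from .preprocess import REFERENCE_SCALE, SCALES

__all__ = [
    "ContrastResult",
    "AgreementResult",
    "SurrogacyDecision",
    "UndefinedTestError",
    "InsufficientPairsError",
    "IncompleteInputError",
    "stress_contrast",
    "contrast_table",
    "spearman_agreement",
    "bland_altman",
    "agreement_table",
    "select_surrogates",
    "decisions_frame",
]

ULTRA_SHORT_SCALES = tuple(s for s in SCALES if s != REFERENCE_SCALE)
STRESS_LEVELS = ("low", "high")

RHO_THRESHOLD = 0.7
ALPHA = 0.05


class UndefinedTestError(ValueError):
    """A contrast group is empty or too small for a t-test."""


class InsufficientPairsError(ValueError):
    """Fewer than the minimum paired epochs for an agreement statistic."""


class IncompleteInputError(ValueError):
    """A feature x scale x stress cell required by the selection rule is absent."""


@dataclass(frozen=True)
class ContrastResult:
    """Low-vs-high t-test for one feature at one scale.

    ``trend`` is ``up``/``down`` by the sign of (mean_high - mean_low), with
    the ``_sig`` suffix when p < alpha; a zero mean difference is marked
    ``down`` with ``tie=True`` so the mark is deterministic.
    """

    feature: str
    scale: str
    t_stat: float
    p_value: float
    trend: str
    n_low: int
    n_high: int
    tie: bool = False

    @property
    def significant(self) -> bool:
        return self.trend.endswith("_sig")

    @property
    def direction(self) -> str:
        return "up" if self.trend.startswith("up") else "down"


@dataclass(frozen=True)
class AgreementResult:
    """Spearman + Bland-Altman agreement of an ultra-short scale vs 5 min."""

    feature: str
    scale: str
    stress: str
    rho: float
    rho_p: float
    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int
    pair_means: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore[assignment]
    pair_diffs: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class SurrogacyDecision:
    feature: str
    scale: str
    selected: bool
    reasons: tuple[str, ...]


def _group_values(table: pd.DataFrame, feature: str, scale: str, label: str) -> np.ndarray:
    vals = table.loc[(table["scale"] == scale) & (table["label"] == label), feature]
    return vals.dropna().to_numpy(dtype=float)


def stress_contrast(
    table: pd.DataFrame, feature: str, scale: str,
    alpha: float = ALPHA, welch: bool = False,
) -> ContrastResult:
    """Two-sided Student's t-test of a feature between stress levels.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.  Missing feature values are excluded before testing.
    """
    low = _group_values(table, feature, scale, "low")
    high = _group_values(table, feature, scale, "high")
    if low.size < 2 or high.size < 2:
        raise UndefinedTestError(
            f"{feature}@{scale}: need >= 2 non-missing epochs per group "
            f"(got {low.size} low, {high.size} high)"
        )
    t_stat, p_value = stats.ttest_ind(high, low, equal_var=not welch)
    diff = float(np.mean(high) - np.mean(low))
    tie = diff == 0.0
    direction = "up" if diff > 0 else "down"
    trend = f"{direction}_sig" if p_value < alpha else direction
    return ContrastResult(
        feature=feature, scale=scale, t_stat=float(t_stat), p_value=float(p_value),
        trend=trend, n_low=int(low.size), n_high=int(high.size), tie=tie,
    )


def contrast_table(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
    scales: Sequence[str] = SCALES,
    alpha: float = ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature, per-scale contrasts with a supplementary Holm column."""
    rows = []
    for scale in scales:
        for feature in features:
            c = stress_contrast(table, feature, scale, alpha=alpha, welch=welch)
            rows.append({
                "feature": c.feature, "scale": c.scale, "t_stat": c.t_stat,
                "p_value": c.p_value, "trend": c.trend, "tie": c.tie,
                "n_low": c.n_low, "n_high": c.n_high,
            })
    df = pd.DataFrame(rows)
    # Holm adjustment across the feature family within each scale.
    df["p_holm"] = np.nan
    for scale in scales:
        mask = df["scale"] == scale
        df.loc[mask, "p_holm"] = multipletests(df.loc[mask, "p_value"], method="holm")[1]
    return df


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho/p; NaN (not a warning) when either input is constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _paired_values(
    table: pd.DataFrame, feature: str, scale: str, stress: str,
    reference: str = REFERENCE_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Ultra-short and 5-min values aligned on (record_id, parent_index)."""
    sub = table[table["label"] == stress]
    short = sub[sub["scale"] == scale].set_index(["record_id", "parent_index"])[feature]
    ref = sub[sub["scale"] == reference].set_index(["record_id", "parent_index"])[feature]
    joined = pd.concat({"short": short, "ref": ref}, axis=1, join="inner").dropna()
    return joined["short"].to_numpy(float), joined["ref"].to_numpy(float)


def spearman_agreement(
    table: pd.DataFrame, feature: str, scale: str, stress: str,
    min_pairs: int = 5,
) -> tuple[float, float]:
    """Spearman rank correlation of paired ultra-short vs 5-min values.

    Average-rank tie handling; p-value from the t-distribution
    approximation.  Requires at least ``min_pairs`` complete pairs.
    """
    x, y = _paired_values(table, feature, scale, stress)
    if x.size < min_pairs:
        raise InsufficientPairsError(
            f"{feature}@{scale}/{stress}: {x.size} pairs < {min_pairs}"
        )
    return _spearman(x, y)


def bland_altman(
    table: pd.DataFrame, feature: str, scale: str, stress: str,
    min_pairs: int = 5,
) -> AgreementResult:
    """Spearman + Bland-Altman agreement for one feature/scale/stress cell.

    Differences are ultra-short minus 5-min; limits of agreement are
    bias +/- 1.96 times the sample SD of the differences.  The paired means
    and differences are returned as plot data.
    """
    x, y = _paired_values(table, feature, scale, stress)
    if x.size < min_pairs:
        raise InsufficientPairsError(
            f"{feature}@{scale}/{stress}: {x.size} pairs < {min_pairs}"
        )
    rho, rho_p = _spearman(x, y)
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        feature=feature, scale=scale, stress=stress,
        rho=float(rho), rho_p=float(rho_p),
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n_pairs=int(x.size), pair_means=(x + y) / 2.0, pair_diffs=d,
    )


def agreement_table(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
    scales: Sequence[str] = ULTRA_SHORT_SCALES,
    stresses: Sequence[str] = STRESS_LEVELS,
) -> pd.DataFrame:
    """All agreement cells as a flat frame (features x scales x stress)."""
    rows = []
    for feature in features:
        for scale in scales:
            for stress in stresses:
                a = bland_altman(table, feature, scale, stress)
                rows.append({
                    "feature": a.feature, "scale": a.scale, "stress": a.stress,
                    "rho": a.rho, "rho_p": a.rho_p, "bias": a.bias,
                    "loa_low": a.loa_low, "loa_high": a.loa_high,
                    "n_pairs": a.n_pairs,
                })
    return pd.DataFrame(rows)


def select_surrogates(
    contrasts: Iterable[ContrastResult],
    agreements: Iterable[AgreementResult],
    scales: Sequence[str] = ULTRA_SHORT_SCALES,
    rho_threshold: float = RHO_THRESHOLD,
    rho_alpha: float = ALPHA,
) -> list[SurrogacyDecision]:
    """Apply the surrogate-selection rule per feature and ultra-short scale.

    A feature is selected at scale ``s`` iff (a) its trend at ``s`` and at
    5 min are both significant with the same direction, and (b) rho exceeds
    ``rho_threshold`` with p < ``rho_alpha`` at ``s`` for both stress levels.
    The returned decisions carry the pass/fail reason for every criterion.
    """
    cmap = {(c.feature, c.scale): c for c in contrasts}
    amap = {(a.feature, a.scale, a.stress): a for a in agreements}
    features = sorted({f for f, _ in cmap}, key=lambda f: FEATURE_NAMES.index(f)
                      if f in FEATURE_NAMES else len(FEATURE_NAMES))
    decisions = []
    for feature in features:
        ref = cmap.get((feature, REFERENCE_SCALE))
        if ref is None:
            raise IncompleteInputError(f"missing contrast for {feature}@{REFERENCE_SCALE}")
        for scale in scales:
            c = cmap.get((feature, scale))
            if c is None:
                raise IncompleteInputError(f"missing contrast for {feature}@{scale}")
            reasons = []
            ok = True
            if c.significant and ref.significant and c.direction == ref.direction:
                reasons.append("(a) concordant significant trend: pass")
            else:
                ok = False
                reasons.append(
                    "(a) concordant significant trend: fail "
                    f"[{scale}: {c.trend}, {REFERENCE_SCALE}: {ref.trend}]"
                )
            for stress in STRESS_LEVELS:
                a = amap.get((feature, scale, stress))
                if a is None:
                    raise IncompleteInputError(
                        f"missing agreement for {feature}@{scale}/{stress}"
                    )
                if a.rho > rho_threshold and a.rho_p < rho_alpha:
                    reasons.append(f"(b) rho[{stress}]={a.rho:.3f}: pass")
                else:
                    ok = False
                    reasons.append(
                        f"(b) rho[{stress}]={a.rho:.3f} (p={a.rho_p:.3g}): fail "
                        f"[need rho > {rho_threshold} and p < {rho_alpha}]"
                    )
            decisions.append(SurrogacyDecision(feature, scale, ok, tuple(reasons)))
    return decisions


def decisions_frame(decisions: Sequence[SurrogacyDecision]) -> pd.DataFrame:
    df = pd.DataFrame([
        {"feature": d.feature, "scale": d.scale, "selected": d.selected,
         "reasons": "; ".join(d.reasons)}
        for d in decisions
    ])
    return df


def all_scale_surrogates(decisions: Sequence[SurrogacyDecision],
                         scales: Sequence[str] = ULTRA_SHORT_SCALES) -> list[str]:
    """Features selected at every ultra-short scale."""
    by_feature: dict[str, set[str]] = {}
    for d in decisions:
        if d.selected:
            by_feature.setdefault(d.feature, set()).add(d.scale)
    need = set(scales)
    ordered = [f for f in FEATURE_NAMES if by_feature.get(f, set()) >= need]
    extra = [f for f in by_feature if f not in FEATURE_NAMES and by_feature[f] >= need]
    return ordered + sorted(extra)


__all__.append("all_scale_surrogates")
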