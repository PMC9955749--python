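"""Stress contrasts, rank agreement, Bland-Altman, and the selection rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrvstress import (
    bland_altman,
    select_surrogates,
    spearman_agreement,
    stress_contrast,
)
from hrvstress.surrogacy_stats import (
    InsufficientPairsError,
    agreement_table,
    all_scale_surrogates,
    contrast_table,
)

SCALES5 = ("30s", "1min", "2min", "3min", "5min")
ULTRA = ("30s", "1min", "2min", "3min")


def make_table(feature_values, feature="F"):
    """Feature table from {scale: {label: values}} keyed by parent index."""
    rows = []
    for scale, by_label in feature_values.items():
        idx = 0
        for label, values in by_label.items():
            for v in values:
                rows.append({"record_id": "r", "parent_index": idx, "scale": scale,
                             "label": label, feature: v})
                idx += 1
    return pd.DataFrame(rows)


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t statistic and p-value."""
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (sum(a) / na - sum(b) / nb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def spearman_oracle(x, y):
    """Average-rank Spearman via explicit rank construction + Pearson."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestStressContrast:
    def test_identical_groups_tie(self):
        table = make_table({"5min": {"low": [5, 6, 7], "high": [5, 6, 7]}})
        c = stress_contrast(table, "F", "5min")
        assert c.t_stat == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)
        assert c.trend == "down" and c.tie  # deterministic zero-difference rule

    def test_matches_pooled_variance_oracle(self, rng):
        for _ in range(50):
            a = list(rng.normal(0, 1, size=rng.integers(4, 12)))
            b = list(rng.normal(0.5, 1.5, size=rng.integers(4, 12)))
            table = make_table({"5min": {"low": a, "high": b}})
            c = stress_contrast(table, "F", "5min")
            t, p = pooled_t_oracle(b, a)
            assert c.t_stat == pytest.approx(t, rel=1e-9)
            assert c.p_value == pytest.approx(p, rel=1e-9)

    def test_large_separation_gives_significant_down_trend(self, rng):
        low = rng.normal(850, 10, size=40)
        high = rng.normal(810, 10, size=40)  # 4 pooled SDs below
        table = make_table({"5min": {"low": list(low), "high": list(high)}})
        c = stress_contrast(table, "F", "5min")
        assert c.trend == "down_sig"

    def test_affine_invariance_of_p_value(self, rng):
        a = list(rng.normal(0, 1, 8))
        b = list(rng.normal(1, 1, 9))
        t1 = make_table({"5min": {"low": a, "high": b}})
        t2 = make_table({"5min": {"low": [3 * v + 7 for v in a],
                                  "high": [3 * v + 7 for v in b]}})
        c1 = stress_contrast(t1, "F", "5min")
        c2 = stress_contrast(t2, "F", "5min")
        assert c1.p_value == pytest.approx(c2.p_value, rel=1e-9)

    def test_holm_column_is_no_smaller(self, feature_table):
        df = contrast_table(feature_table)
        assert (df["p_holm"] >= df["p_value"] - 1e-15).all()


def paired_table(pairs_by_stress, feature="F", scale="30s"):
    """Table with (ultra, 5min) value pairs per parent for one feature."""
    rows = []
    idx = 0
    for stress, pairs in pairs_by_stress.items():
        for u, f in pairs:
            rows.append({"record_id": "r", "parent_index": idx, "scale": scale,
                         "label": stress, feature: u})
            rows.append({"record_id": "r", "parent_index": idx, "scale": "5min",
                         "label": stress, feature: f})
            idx += 1
    return pd.DataFrame(rows)


class TestSpearmanAgreement:
    def test_perfect_monotone(self):
        pairs = [(i, i**2) for i in range(1, 9)]
        table = paired_table({"low": pairs})
        rho, p = spearman_agreement(table, "F", "30s", "low")
        assert rho == pytest.approx(1.0)

    def test_matches_rank_oracle_with_ties(self, rng):
        x = [1, 2, 2, 3, 5]
        y = [2, 1, 3, 4, 4]
        table = paired_table({"low": list(zip(x, y))})
        rho, _ = spearman_agreement(table, "F", "30s", "low")
        assert rho == pytest.approx(spearman_oracle(x, y), rel=1e-12)
        for _ in range(50):
            x = list(rng.integers(0, 6, size=8))
            y = list(rng.integers(0, 6, size=8))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            table = paired_table({"low": list(zip(x, y))})
            rho, _ = spearman_agreement(table, "F", "30s", "low")
            assert rho == pytest.approx(spearman_oracle(x, y), rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = list(rng.normal(size=12))
        y = list(rng.normal(size=12))
        base = spearman_agreement(paired_table({"low": list(zip(x, y))}), "F", "30s", "low")[0]
        up = spearman_agreement(
            paired_table({"low": [(np.exp(a), b) for a, b in zip(x, y)]}), "F", "30s", "low")[0]
        down = spearman_agreement(
            paired_table({"low": [(-a, b) for a, b in zip(x, y)]}), "F", "30s", "low")[0]
        assert up == pytest.approx(base, rel=1e-12)
        assert down == pytest.approx(-base, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        table = paired_table({"low": [(1, 1), (2, 2)]})
        with pytest.raises(InsufficientPairsError):
            spearman_agreement(table, "F", "30s", "low")

    def test_rank_identity_of_lf_hf_ratios(self, feature_table):
        """LF/HF, LFnu and HFnu are monotone transforms of one another, so
        their rank agreement with the 5-min reference is identical."""
        for scale in ULTRA:
            for stress in ("low", "high"):
                rhos = [
                    spearman_agreement(feature_table, f, scale, stress)[0]
                    for f in ("LF_HF", "LFnu", "HFnu")
                ]
                assert rhos[0] == pytest.approx(rhos[1], abs=1e-12)
                assert rhos[1] == pytest.approx(rhos[2], abs=1e-12)


class TestBlandAltman:
    def test_identical_methods(self):
        pairs = [(v, v) for v in [1.0, 2.0, 3.0, 4.0, 5.0]]
        a = bland_altman(paired_table({"low": pairs}), "F", "30s", "low")
        assert a.bias == 0 and a.loa_low == 0 and a.loa_high == 0

    def test_forced_loa(self):
        pairs = [(4.0, 5.0), (5.0, 5.0), (6.0, 5.0), (5.0, 5.0), (5.0, 5.0)]
        # differences [-1, 0, 1, 0, 0] -> replaced below with exactly [-1,0,1]
        pairs = [(4.0, 5.0), (5.0, 5.0), (6.0, 5.0)]
        a = bland_altman(paired_table({"low": pairs}), "F", "30s", "low", min_pairs=3)
        assert a.bias == pytest.approx(0.0)
        assert a.loa_low == pytest.approx(-1.96)
        assert a.loa_high == pytest.approx(1.96)

    def test_antisymmetry_under_method_exchange(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.normal(5, 1, size=(8, 2))]
        fwd = bland_altman(paired_table({"low": pairs}), "F", "30s", "low")
        swapped = [(b, a) for a, b in pairs]
        rev = bland_altman(paired_table({"low": swapped}), "F", "30s", "low")
        assert rev.bias == pytest.approx(-fwd.bias, rel=1e-12)
        assert (rev.loa_high - rev.loa_low) == pytest.approx(
            fwd.loa_high - fwd.loa_low, rel=1e-12)

    def test_loa_width_narrows_with_epoch_length(self, feature_table):
        """MeanNN agreement with the 5-min value tightens as epochs lengthen."""
        def width(scale):
            out = [bland_altman(feature_table, "MeanNN", scale, s)
                   for s in ("low", "high")]
            return np.mean([a.loa_high - a.loa_low for a in out])
        assert width("30s") > width("3min")


class TestSelectSurrogates:
    def _inputs(self, table):
        contrasts = [stress_contrast(table, "F", s) for s in SCALES5]
        agreements = [bland_altman(table, "F", s, stress)
                      for s in ULTRA for stress in ("low", "high")]
        return contrasts, agreements

    def _stable_feature_table(self, rng, noisy_30s=False):
        """Parent-level values propagated unchanged to every scale (rho = 1),
        optionally buried in independent noise at 30 s only."""
        rows = []
        idx = 0
        for label, loc in (("low", 100.0), ("high", 160.0)):
            for _ in range(20):
                v = rng.normal(loc, 5)
                for scale in SCALES5:
                    val = v
                    if noisy_30s and scale == "30s":
                        # swamps the within-level correlation (rho ~ 0.2)
                        # while the 60-unit group separation stays detectable
                        val = v + rng.normal(0, 25)
                    rows.append({"record_id": "r", "parent_index": idx,
                                 "scale": scale, "label": label, "F": val})
                idx += 1
        return pd.DataFrame(rows)

    def test_scale_stable_feature_selected_everywhere(self, rng):
        table = self._stable_feature_table(rng)
        decisions = select_surrogates(*self._inputs(table), ULTRA)
        assert all(d.selected for d in decisions)
        assert all_scale_surrogates(decisions, ULTRA) == ["F"]

    def test_noise_at_30s_rejected_for_correlation_criterion(self, rng):
        table = self._stable_feature_table(rng, noisy_30s=True)
        decisions = select_surrogates(*self._inputs(table), ULTRA)
        by_scale = {d.scale: d for d in decisions}
        assert not by_scale["30s"].selected
        failed = [r for r in by_scale["30s"].reasons if "fail" in r]
        assert failed and all(r.startswith("(b)") for r in failed)
        assert all(by_scale[s].selected for s in ("1min", "2min", "3min"))
        assert all_scale_surrogates(decisions, ULTRA) == []

    def test_decision_monotone_in_rho(self, rng):
        """Raising rho (less 30-s noise) never un-selects a feature."""
        table_noisy = self._stable_feature_table(rng, noisy_30s=True)
        table_clean = self._stable_feature_table(rng, noisy_30s=False)
        sel_noisy = {d.scale: d.selected
                     for d in select_surrogates(*self._inputs(table_noisy), ULTRA)}
        sel_clean = {d.scale: d.selected
                     for d in select_surrogates(*self._inputs(table_clean), ULTRA)}
        for scale in ULTRA:
            assert sel_clean[scale] >= sel_noisy[scale]

    def test_agreement_table_covers_all_cells(self, feature_table):
        df = agreement_table(feature_table, ["MeanNN", "SDNN"], ULTRA)
        assert len(df) == 2 * 4 * 2
        assert (df["loa_low"] <= df["bias"] + 1e-12).all()
        assert (df["bias"] <= df["loa_high"] + 1e-12).all()
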