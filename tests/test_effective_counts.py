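import math

import numpy as np
import pytest

from ccbmd import (
    DatasetError,
    or_from_counts,
    propagate_group,
    se_log_or,
    totals_summary,
    wang_objective,
    wang_referent,
)
from ccbmd.datamodel import TotalsSummary
from ccbmd.effective_counts import effective_dataset


class TestPropagateGroup:
    @pytest.mark.parametrize(
        "a0, b0, or_i, n_i, expected_cases",
        [
            (18, 110, 5.30, 214, 99),   # Pu highest bladder group
            (21, 242, 3.18, 206, 45),   # Steinmaus highest lung group
            (109, 431, 1.13, 576, 128), # Mostafa group 2 at its effective n
            (109, 431, 1.28, 292, 71),  # Mostafa group 3
        ],
    )
    def test_reproduces_published_effective_cases(self, a0, b0, or_i, n_i, expected_cases):
        a, b = propagate_group(a0, b0, or_i, n_i)
        assert round(a) == expected_cases
        assert a + b == pytest.approx(n_i)

    def test_or_one_keeps_referent_proportion(self):
        a, b = propagate_group(30, 70, 1.0, 200)
        assert a / (a + b) == pytest.approx(30 / 100)

    def test_or_reconstruction_exact(self):
        """The propagated cells return the input OR to 1e-9."""
        for or_i in (0.3, 1.0, 2.7, 9.4):
            a, b = propagate_group(18, 110, or_i, 214)
            assert or_from_counts(a, b, 18, 110) == pytest.approx(or_i, rel=1e-9)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(DatasetError):
            propagate_group(0, 110, 2.0, 100)


#: the one source row where propagating the printed (2-decimal) OR lands on
#: the other side of the half-count boundary: 47.467 rounds to 47 but the
#: source prints 48 (consistent with an unrounded OR near 1.40).
OFF_BY_ONE_ROWS = {("Ferreccio2000", "lung", "200-799")}


def test_fixture_regression_propagation(all_datasets):
    """Propagating each study's printed referent effective counts reproduces
    every printed treatment-group effective case count after rounding, except
    one documented row that is still within one count."""
    for ds in all_datasets:
        a0 = ds.referent.effective_cases
        b0 = ds.referent.effective_noncases
        for g in ds.groups[1:]:
            a, _ = propagate_group(a0, b0, g.or_point, g.n_subjects_effective)
            key = (ds.study_id, ds.endpoint, g.label)
            if key in OFF_BY_ONE_ROWS:
                assert abs(a - g.effective_cases) < 1.0, key
            else:
                assert round(a) == g.effective_cases, key


def _self_consistent_totals(a0, b0, ors, n_exposed_each):
    """Build totals for a synthetic study whose adjusted ORs equal its crude
    ORs and whose CI widths follow the Woolf SE — the raw referent is then
    exactly 'effective'."""
    from scipy.stats import norm

    z = norm.ppf(0.975)
    lows, highs = [], []
    for or_i, n_i in zip(ors, n_exposed_each):
        a, b = propagate_group(a0, b0, or_i, n_i)
        se = se_log_or(a, b, a0, b0)
        lows.append(or_i * math.exp(-z * se))
        highs.append(or_i * math.exp(z * se))
    return TotalsSummary(
        n_referent=a0 + b0,
        n_total=a0 + b0 + sum(n_exposed_each),
        mean_or=float(np.mean(ors)),
        mean_or_low=float(np.mean(lows)),
        mean_or_high=float(np.mean(highs)),
    )


class TestWangReferent:
    def test_self_consistent_case_returns_raw_referent(self):
        """When the reported ORs and CI widths are exactly the crude ones, the
        raw referent counts minimize the objective (brute-force confirmed)."""
        tot = _self_consistent_totals(20, 180, [3.0], [200])
        a0, b0, ss = wang_referent(tot, referent_raw=(20, 180))
        assert (a0, b0) == (20.0, 180.0)
        assert ss == pytest.approx(0.0, abs=1e-10)
        # brute-force oracle over the full integer grid
        grid = np.arange(1, 200)
        vals = [wang_objective(a, tot) for a in grid]
        assert grid[int(np.argmin(vals))] == 20

    def test_flat_objective_returns_raw_with_single_or_one_group(self):
        """A single non-referent group with OR = 1 and a CI exactly matching
        the raw-referent Woolf width carries no information beyond the raw
        counts; the search keeps them."""
        tot = _self_consistent_totals(50, 50, [1.0], [100])
        a0, b0, _ = wang_referent(tot, referent_raw=(50, 50))
        assert (a0, b0) == (50.0, 50.0)

    def test_low_incidence_root_preferred(self, bladder):
        """The CI-matching objective has a low- and a high-incidence root; the
        published counts correspond to the low one (e.g. Wu: 27, not 196)."""
        wu = bladder[4]
        a0, _, _ = wang_referent(totals_summary(wu))
        assert a0 == 27.0

    @pytest.mark.parametrize(
        "endpoint, study, printed",
        [
            ("bladder", "Ferreccio2000", 19),
            ("bladder", "Pu2007", 18),
            ("bladder", "Wu2013", 27),
            ("lung", "Ferreccio2000", 32),
            ("lung", "Steinmaus2013", 21),
        ],
    )
    def test_reproduces_printed_referent_counts(self, endpoint, study, printed, bladder, lung):
        ds = next(
            d for d in (bladder if endpoint == "bladder" else lung) if d.study_id == study
        )
        a0, b0, _ = wang_referent(totals_summary(ds))
        assert a0 == printed
        assert a0 + b0 == ds.referent.n_subjects


class TestEffectiveDataset:
    def test_rounding_preserves_group_totals(self, pu):
        eff = effective_dataset(pu, rounding="nearest_integer", referent=(18, 110))
        for g in eff.groups:
            assert g.effective_cases == round(g.effective_cases)
            assert g.effective_cases + g.effective_noncases == g.n_subjects_effective

    def test_real_counts_conserved_before_rounding(self, pu):
        eff = effective_dataset(pu, rounding="gamma_real", referent=(18, 110))
        for g in eff.groups:
            assert g.effective_cases + g.effective_noncases == pytest.approx(
                g.n_subjects_effective, abs=1e-9
            )

    def test_all_or_one_mirrors_referent_fraction(self):
        import io

        from ccbmd import read_dataset

        csv = (
            "group_label,or,or_low,or_high,cases,noncases,n\n"
            "0-1,1,,,30,70,100\n"
            "1-2,1.0,0.5,2.0,40,60,100\n"
            "2-3,1.0,0.5,2.0,10,90,100\n"
        )
        ds = read_dataset(io.StringIO(csv))
        eff = effective_dataset(ds, referent=(30, 70))
        for g in eff.groups:
            assert g.effective_cases / g.n_subjects_effective == pytest.approx(0.3)

    def test_unknown_rounding_mode_rejected(self, pu):
        with pytest.raises(DatasetError):
            effective_dataset(pu, rounding="ceil")
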