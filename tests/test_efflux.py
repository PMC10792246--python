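import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effluxkit.efflux import (
    MOCK,
    NO_ACCEPTOR,
    WITH_ACCEPTOR,
    WT,
    aggregate_replicates,
    compute_efflux_fraction,
    compute_specific_efflux,
    correct_leakage,
    normalize_to_wt,
    process_well_table,
    renilla_adjust,
    summarize_activity,
)
from effluxkit.errors import (
    DegenerateWellError,
    ExperimentInvalidError,
    InsufficientReplicatesError,
    PairingError,
)


class TestEffluxFraction:
    def test_basic_arithmetic(self):
        assert compute_efflux_fraction(300, 700) == pytest.approx(0.30)

    def test_zero_medium(self):
        assert compute_efflux_fraction(0, 500) == 0.0

    def test_scale_invariance_example(self):
        assert compute_efflux_fraction(300, 700) == compute_efflux_fraction(600, 1400)

    def test_degenerate_well(self):
        with pytest.raises(DegenerateWellError):
            compute_efflux_fraction(0, 0)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_efflux_fraction(-1, 10)

    @given(
        medium=st.floats(0, 1e6),
        lysate=st.floats(0, 1e6),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_property(self, medium, lysate, c):
        if medium + lysate <= 0 or (medium + lysate) * c <= 0:
            return
        f1 = compute_efflux_fraction(medium, lysate)
        f2 = compute_efflux_fraction(medium * c, lysate * c)
        assert f1 == pytest.approx(f2, abs=1e-9)
        assert 0.0 <= f1 <= 1.0


class TestCorrections:
    def test_leakage(self):
        assert correct_leakage(0.30, 0.05) == pytest.approx(0.25)

    def test_leakage_exact_zero(self):
        assert correct_leakage(0.05, 0.05) == pytest.approx(0.0)

    def test_leakage_negative_not_clamped(self):
        assert correct_leakage(0.03, 0.05) == pytest.approx(-0.02)

    def test_mock_subtraction(self):
        assert compute_specific_efflux(0.25, 0.05) == pytest.approx(0.20)

    def test_mock_vs_itself(self):
        assert compute_specific_efflux(0.05, 0.05) == 0.0

    def test_mock_subtraction_negative_retained(self):
        assert compute_specific_efflux(0.04, 0.05) == pytest.approx(-0.01)


class TestNormalization:
    def test_half_activity(self):
        raw, rep = normalize_to_wt(0.20, 0.40)
        assert raw == pytest.approx(50.0) and rep == pytest.approx(50.0)

    def test_identity(self):
        raw, rep = normalize_to_wt(0.40, 0.40)
        assert raw == pytest.approx(100.0)

    def test_negative_clamped_only_in_report(self):
        raw, rep = normalize_to_wt(-0.01, 0.40)
        assert raw == pytest.approx(-2.5)
        assert rep == 0.0

    def test_invalid_wt(self):
        with pytest.raises(ExperimentInvalidError):
            normalize_to_wt(0.2, 0.0)


class TestRenilla:
    def test_equal_renilla_identity(self):
        assert renilla_adjust(0.2, 500, 500) == pytest.approx(0.2)

    def test_double_renilla_halves(self):
        assert renilla_adjust(0.2, 1000, 500) == pytest.approx(0.1)

    def test_zero_luminescence(self):
        with pytest.raises(ValueError):
            renilla_adjust(0.2, 0, 500)


class TestAggregate:
    def test_two_values(self):
        mean, sd, n = aggregate_replicates([79, 81])
        assert (mean, n) == (80.0, 2)
        assert sd == pytest.approx(math.sqrt(2))

    def test_constant(self):
        assert aggregate_replicates([50, 50, 50, 50]) == (50.0, 0.0, 4)

    def test_hand_arithmetic(self):
        # deviations from 80: -14, 12, -1, 3 -> SS 350, /3, sqrt
        mean, sd, n = aggregate_replicates([66, 92, 79, 83])
        assert mean == pytest.approx(80.0)
        assert sd == pytest.approx(math.sqrt(350 / 3))

    def test_insufficient(self):
        with pytest.raises(InsufficientReplicatesError):
            aggregate_replicates([80])


def _well(construct, condition, medium, lysate, exp=1, rep=1, renilla=np.nan):
    return {
        "construct": construct,
        "condition": condition,
        "medium": medium,
        "lysate": lysate,
        "renilla": renilla,
        "experiment": exp,
        "replicate": rep,
    }


def _toy_experiment(exp=1, scale=1.0):
    """Noise-free wells: leakage 0.05, mock unspecific 0.04, WT specific 0.25."""
    def signals(frac, total=1000.0):
        total *= scale
        return total * frac, total * (1 - frac)

    rows = []
    m, l = signals(0.05)
    rows.append(_well(MOCK, NO_ACCEPTOR, m, l, exp))
    m, l = signals(0.09)
    rows.append(_well(MOCK, WITH_ACCEPTOR, m, l, exp))
    m, l = signals(0.34)  # 0.25 specific + 0.04 + 0.05
    rows.append(_well(WT, WITH_ACCEPTOR, m, l, exp))
    m, l = signals(0.215)  # 0.125 specific -> 50% of WT
    rows.append(_well("p.X100Y", WITH_ACCEPTOR, m, l, exp))
    return rows


class TestProcessWellTable:
    def test_recovers_known_activities(self):
        df = pd.DataFrame(_toy_experiment(1) + _toy_experiment(2))
        res = process_well_table(df)
        by = res.set_index(["construct", "experiment"])
        assert by.loc[(WT, 1), "relative_activity"] == pytest.approx(100.0)
        assert by.loc[("p.X100Y", 1), "relative_activity"] == pytest.approx(50.0)

    def test_wt_is_100_per_experiment(self):
        df = pd.DataFrame(_toy_experiment(1) + _toy_experiment(2, scale=7.3))
        res = process_well_table(df)
        wt = res[res["construct"] == WT]["relative_activity"]
        assert np.allclose(wt, 100.0)

    def test_end_to_end_scale_invariance(self):
        base = process_well_table(pd.DataFrame(_toy_experiment()))
        scaled_rows = _toy_experiment()
        for r in scaled_rows:
            r["medium"] *= 42.0
            r["lysate"] *= 42.0
        scaled = process_well_table(pd.DataFrame(scaled_rows))
        assert np.allclose(
            base["relative_activity"], scaled["relative_activity"], atol=1e-9
        )

    def test_missing_mock_no_acceptor(self):
        rows = [r for r in _toy_experiment() if r["condition"] != NO_ACCEPTOR]
        with pytest.raises(PairingError):
            process_well_table(pd.DataFrame(rows))

    def test_missing_wt(self):
        rows = [r for r in _toy_experiment() if r["construct"] != WT]
        with pytest.raises(PairingError):
            process_well_table(pd.DataFrame(rows))

    def test_correction_order_matters(self):
        """Normalizing to WT before mock subtraction gives a different answer.

        The pipeline's fixed order is fraction -> leakage -> mock -> WT;
        this guards against permuting mock subtraction and normalization.
        """
        df = pd.DataFrame(_toy_experiment())
        res = process_well_table(df).set_index("construct")
        # wrong order: normalize leakage-corrected fractions directly
        wrong = (
            100.0
            * res.loc["p.X100Y", "leakage_corrected_fraction"]
            / res.loc[WT, "leakage_corrected_fraction"]
        )
        assert wrong != pytest.approx(res.loc["p.X100Y", "relative_activity"])

    def test_summarize_activity(self):
        df = pd.DataFrame(_toy_experiment(1) + _toy_experiment(2))
        summ = summarize_activity(process_well_table(df))
        row = summ.set_index("construct").loc["p.X100Y"]
        assert row["mean_activity"] == pytest.approx(50.0)
        assert row["sd"] == pytest.approx(0.0)
        assert row["n"] == 2
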