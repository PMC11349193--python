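"""JATP conversion: proton-rate accounting and P/O weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xflux import (
    AssayConfig,
    atp_glyc,
    atp_ox,
    get_energetics,
    ocr_components,
    ppr_glyc,
    ppr_resp,
    ppr_total,
    respiratory_fraction,
)
from xflux.errors import ValidationError

CFG = AssayConfig()

# independent closed-form evaluation of the ionized CO2-acid fraction at
# the XF DMEM constants (pH 7.4, pK1 6.093)
F_RESP = 10.0 ** (7.4 - 6.093) / (1.0 + 10.0 ** (7.4 - 6.093))


class TestScalarOps:
    def test_respiratory_fraction_at_dmem_constants(self):
        assert respiratory_fraction(7.4, 6.093) == pytest.approx(F_RESP, rel=1e-15)
        assert respiratory_fraction(7.4, 6.093) == pytest.approx(0.9530, abs=5e-5)

    def test_respiratory_fraction_is_half_at_pk1(self):
        assert respiratory_fraction(6.5, 6.5) == 0.5

    def test_respiratory_fraction_monotone_in_ph(self):
        phs = np.linspace(3.0, 10.0, 50)
        vals = [respiratory_fraction(p, 6.093) for p in phs]
        assert all(0 < v < 1 for v in vals)
        assert np.all(np.diff(vals) > 0)
        assert vals[0] < 1e-3  # pH << pK1 limit

    def test_ppr_total_divides_by_buffer_factor(self):
        assert ppr_total(60.0, CFG) == pytest.approx(600.0)
        assert ppr_total(0.0, CFG) == 0.0
        double_bf = AssayConfig(buffer_factor=0.2)
        assert ppr_total(60.0, double_bf) == pytest.approx(300.0)

    def test_ppr_resp_composes_fraction_and_stoichiometry(self):
        assert ppr_resp(100.0, CFG) == pytest.approx(100.0 * F_RESP, rel=1e-15)
        assert ppr_resp(0.0, CFG) == 0.0
        higher_ph = AssayConfig(ph=7.8)
        assert ppr_resp(100.0, higher_ph) > ppr_resp(100.0, CFG)

    def test_ppr_glyc_is_total_minus_respiratory(self):
        assert ppr_glyc(600.0, 100.0 * F_RESP) == pytest.approx(
            600.0 - 100.0 * F_RESP, rel=1e-15
        )
        assert ppr_glyc(600.0, 0.0) == 600.0
        assert ppr_glyc(50.0, 100.0) < 0  # over-correction passes through

    def test_atp_glyc_lactate_plus_oxidized_pyruvate_terms(self):
        glyc = 600.0 - 100.0 * F_RESP
        expected = glyc * 1.0 + 100.0 * 2.0 * 0.167
        assert atp_glyc(glyc, 100.0, CFG) == pytest.approx(expected, rel=1e-15)
        assert atp_glyc(glyc, 100.0, CFG) == pytest.approx(538.10, abs=5e-3)
        assert atp_glyc(0.0, 0.0, CFG) == 0.0
        no_po = AssayConfig(po_glyc=0.0)
        assert atp_glyc(glyc, 100.0, no_po) == pytest.approx(glyc)

    def test_atp_ox_doubles_o2_and_weights_by_po(self):
        assert atp_ox(70.0, 100.0, CFG) == pytest.approx(
            2 * 2.486 * 70 + 2 * 0.121 * 100, rel=1e-15
        )
        assert atp_ox(70.0, 100.0, CFG) == pytest.approx(372.24)
        assert atp_ox(0.0, 0.0, CFG) == 0.0
        assert atp_ox(7.0, 10.0, CFG) == pytest.approx(atp_ox(70.0, 100.0, CFG) / 10)


def test_ocr_components_worked_example():
    comp = ocr_components(120.0, 50.0, 200.0, 20.0)
    assert (comp.mito_basal, comp.coupled_basal, comp.mito_max, comp.coupled_max) == (
        100.0,
        70.0,
        180.0,
        150.0,
    )
    assert comp.negative == []


def test_ocr_components_flags_negative():
    comp = ocr_components(10.0, 5.0, 20.0, 15.0)
    assert "mito_basal" in comp.negative


def test_ocr_components_all_equal_states_give_zero():
    comp = ocr_components(50.0, 50.0, 50.0, 50.0)
    assert comp == ocr_components(50.0, 50.0, 50.0, 50.0)
    assert comp.mito_basal == comp.coupled_max == 0.0


def _partitioned(mito_states, glyco_states=None):
    """Build a PartitionedRates frame for one MITO well (+ optional GLYCO well)."""
    rows = []
    for state, (ocr, ecar) in mito_states.items():
        rows.append(
            dict(plate_id="p1", exp_group="G1", well="A01", assay_type="MITO",
                 state=state, ocr_state=ocr, ecar_state=ecar, n_points=3)
        )
    for state, (ocr, ecar) in (glyco_states or {}).items():
        rows.append(
            dict(plate_id="p1", exp_group="G1", well="B01", assay_type="GLYCO",
                 state=state, ocr_state=ocr, ecar_state=ecar, n_points=3)
        )
    return pd.DataFrame(rows)


MITO_WELL = {
    "basal": (120.0, 30.0),
    "uncoupled": (50.0, 40.0),
    "maxresp": (200.0, 35.0),
    "nonmito": (20.0, 15.0),
}
GLYCO_WELL = {
    "no_glucose": (90.0, 10.0),
    "glucose": (120.0, 60.0),  # ocr_mito = 120 - 20 (group nonmito) = 100
    "max_glyc": (110.0, 95.0),
    "twodg": (80.0, 12.0),
}


def test_get_energetics_matches_hand_composed_chain():
    """Pipeline output equals the composition of the six scalar operations."""
    res = get_energetics(_partitioned(MITO_WELL, GLYCO_WELL), CFG)
    mito_row = res.data[res.data["assay_type"] == "MITO"].iloc[0]
    comp = ocr_components(120.0, 50.0, 200.0, 20.0)
    assert mito_row["atp_basal_ox"] == pytest.approx(
        atp_ox(comp.coupled_basal, comp.mito_basal, CFG), rel=1e-12
    )
    assert mito_row["atp_max_ox"] == pytest.approx(
        atp_ox(comp.coupled_max, comp.mito_max, CFG), rel=1e-12
    )
    assert mito_row["atp_basal_ox"] == pytest.approx(372.24, rel=1e-12)

    glyco_row = res.data[res.data["assay_type"] == "GLYCO"].iloc[0]
    ocr_mito = 120.0 - 20.0
    expected = atp_glyc(
        ppr_glyc(ppr_total(60.0, CFG), ppr_resp(ocr_mito, CFG)), ocr_mito, CFG
    )
    assert glyco_row["atp_basal_glyc"] == pytest.approx(expected, rel=1e-12)
    assert glyco_row["atp_basal_glyc"] == pytest.approx(538.10, abs=5e-3)


def test_get_energetics_all_zero_rates_give_zero_jatp():
    zeros = {s: (0.0, 0.0) for s in MITO_WELL}
    gzeros = {s: (0.0, 0.0) for s in GLYCO_WELL}
    res = get_energetics(_partitioned(zeros, gzeros), CFG)
    vals = res.data[["atp_basal_ox", "atp_max_ox", "atp_basal_glyc", "atp_max_glyc"]]
    assert np.nansum(np.abs(vals.to_numpy())) == 0.0


@settings(max_examples=50, deadline=None)
@given(c=st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
def test_get_energetics_is_linear_in_rates(c):
    base = get_energetics(_partitioned(MITO_WELL, GLYCO_WELL), CFG)
    scaled_states = {s: (o * c, e * c) for s, (o, e) in MITO_WELL.items()}
    scaled_glyco = {s: (o * c, e * c) for s, (o, e) in GLYCO_WELL.items()}
    scaled = get_energetics(_partitioned(scaled_states, scaled_glyco), CFG)
    cols = ["atp_basal_ox", "atp_max_ox", "atp_basal_glyc", "atp_max_glyc"]
    np.testing.assert_allclose(
        scaled.data[cols].to_numpy(dtype=float),
        base.data[cols].to_numpy(dtype=float) * c,
        rtol=1e-9,
        equal_nan=True,
    )


def test_zero_co2_stoichiometry_decouples_glycolytic_jatp_from_ocr():
    """With max_h_per_o2=0 (and no pyruvate-oxidation credit) glycolytic JATP
    is a pure function of ECAR."""
    cfg = AssayConfig(max_h_per_o2=0.0, po_glyc=0.0)
    res1 = get_energetics(_partitioned(MITO_WELL, GLYCO_WELL), cfg)
    shifted = {s: (o + 37.0, e) for s, (o, e) in GLYCO_WELL.items()}
    res2 = get_energetics(_partitioned(MITO_WELL, shifted), cfg)
    g1 = res1.data[res1.data["assay_type"] == "GLYCO"].iloc[0]
    g2 = res2.data[res2.data["assay_type"] == "GLYCO"].iloc[0]
    assert g1["atp_basal_glyc"] == pytest.approx(g2["atp_basal_glyc"], rel=1e-12)
    assert g1["atp_basal_glyc"] == pytest.approx(60.0 / 0.1, rel=1e-12)


def test_max_coupled_mode_nonmito_changes_only_max_ox():
    cfg = AssayConfig(max_coupled_mode="nonmito")
    default = get_energetics(_partitioned(MITO_WELL), CFG).data.iloc[0]
    alt = get_energetics(_partitioned(MITO_WELL), cfg).data.iloc[0]
    assert alt["atp_basal_ox"] == default["atp_basal_ox"]
    # coupled_max becomes maxresp - nonmito = 180 instead of 150
    assert alt["atp_max_ox"] == pytest.approx(2 * 2.486 * 180 + 2 * 0.121 * 180)


def test_subtract_nonglycolytic_lowers_glycolytic_jatp():
    on = AssayConfig(subtract_nonglycolytic=True)
    base = get_energetics(_partitioned(MITO_WELL, GLYCO_WELL), CFG).data
    sub = get_energetics(_partitioned(MITO_WELL, GLYCO_WELL), on).data
    b = base[base["assay_type"] == "GLYCO"].iloc[0]
    s = sub[sub["assay_type"] == "GLYCO"].iloc[0]
    assert s["atp_basal_glyc"] == pytest.approx(b["atp_basal_glyc"] - 10.0 / 0.1)


def test_missing_state_lands_in_quality_report():
    incomplete = {k: v for k, v in MITO_WELL.items() if k != "nonmito"}
    res = get_energetics(_partitioned(incomplete), CFG)
    assert np.isnan(res.data["atp_basal_ox"].iloc[0])
    kinds = {f["kind"] for f in res.quality.flags}
    assert "missing_state" in kinds


def test_negative_rates_flagged_not_clipped():
    weird = dict(MITO_WELL)
    weird["nonmito"] = (150.0, 15.0)  # nonmito > basal
    res = get_energetics(_partitioned(weird), CFG)
    assert res.data["atp_basal_ox"].iloc[0] < atp_ox(70.0, 0.0, CFG)
    assert any(f["kind"] == "negative_component" for f in res.quality.flags)


def test_invalid_buffer_factor_rejected():
    with pytest.raises(ValidationError):
        AssayConfig(buffer_factor=0.0)


def test_assay_config_yaml_round_trip():
    cfg = AssayConfig(ph=7.2, po_oxphos=2.6)
    assert AssayConfig.from_yaml(cfg.to_yaml()) == cfg
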