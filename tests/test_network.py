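"""Network construction: Murray allocation, Poiseuille elements, topology."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coroflow.network import (FluidProperties, StenosisSpec,
                              REST_R_DISTRIBUTION, STRESS_R_DISTRIBUTION,
                              build_network, chain_resistance, murray_split,
                              poiseuille_resistance, stenosis_coefficients,
                              wall_thickness)
from coroflow.synthetic_cohort import reference_patient


@pytest.mark.parametrize("radii,m,q,expected", [
    ([0.2, 0.2], 3, 4.0, [2.0, 2.0]),
    ([0.2, 0.1], 3, 9.0, [8.0, 1.0]),   # r^3 law: 8:1
    ([0.2, 0.1], 3, 0.0, [0.0, 0.0]),
])
def test_murray_split_examples(radii, m, q, expected):
    assert murray_split(radii, m, q) == pytest.approx(expected)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(radii=st.lists(st.floats(0.02, 0.5), min_size=1, max_size=6),
       m=st.floats(2.0, 3.0), q=st.floats(0.0, 50.0))
def test_murray_split_conserves_and_is_equivariant(radii, m, q):
    parts = murray_split(radii, m, q)
    assert parts.sum() == q  # exact, by remainder assignment
    # permuting the radii permutes the allocation
    perm = np.argsort(radii)
    parts_perm = murray_split(np.asarray(radii)[perm], m, q)
    assert parts_perm == pytest.approx(parts[perm], rel=1e-9, abs=1e-12)


def test_murray_split_rejects_empty_and_nonpositive():
    with pytest.raises(ValueError):
        murray_split([], 3, 1.0)
    with pytest.raises(ValueError):
        murray_split([0.1, -0.2], 3, 1.0)


def test_poiseuille_resistance_value_and_scaling():
    fluid = FluidProperties()
    r = poiseuille_resistance(0.2, 3.0, fluid)
    assert r == pytest.approx(0.96 / (math.pi * 0.0016), rel=1e-12)  # ≈190.99
    assert poiseuille_resistance(0.2, 6.0, fluid) == pytest.approx(2 * r)
    assert poiseuille_resistance(0.4, 3.0, fluid) == pytest.approx(r / 16)


@pytest.mark.parametrize("radius,expected", [(0.2, 0.02), (1.0, 0.1)])
def test_wall_thickness_tenth_of_radius(radius, expected):
    assert wall_thickness(radius) == pytest.approx(expected)


def test_wall_thickness_rejects_nonpositive():
    with pytest.raises(ValueError):
        wall_thickness(0.0)


def test_stenosis_spec_validation():
    with pytest.raises(ValueError):
        StenosisSpec(degree=1.0, length=15.0, ref_radius=0.18)
    s = StenosisSpec(degree=0.5, length=15.0, ref_radius=0.2)
    assert s.throat_radius == pytest.approx(0.1)
    assert s.length_cm == pytest.approx(1.5)


def test_stenosis_coefficients_closed_form():
    fluid = FluidProperties()
    s = StenosisSpec(degree=0.5, length=15.0, ref_radius=0.2, kt=1.52)
    r_visc, k_turb = stenosis_coefficients(s, fluid)
    assert r_visc == pytest.approx(8 * 0.04 * 1.5 / (math.pi * 0.1**4), rel=1e-12)
    a0 = math.pi * 0.04
    assert k_turb == pytest.approx(1.52 * 1.06 / (2 * a0**2) * 9.0, rel=1e-12)


def test_build_network_routes_lesion_to_correct_branch():
    pat = reference_patient(lesion_vessel="LAD")
    net = build_network(pat, "pre", "rest")
    assert net.branch("LAD").stenosis is not None
    assert net.branch("LCx").stenosis is None
    assert net.branch("RCA").stenosis is None
    # right-dominant default tree: LM feeds LAD and LCx, RCA off the root
    assert [s.name for s in net.branch("LAD").chain] == ["LM", "LAD"]
    assert [s.name for s in net.branch("RCA").chain] == ["RCA"]
    # left branches carry the LV-derived Pim, the RCA the RV-derived one
    assert net.branch("LAD").outlet.pim.values.max() == pytest.approx(
        pat.pre.lv_peak, abs=1e-3)
    assert net.branch("RCA").outlet.pim.values.max() == pytest.approx(
        4 * pat.pre.tr_velocity**2 + 5.0, abs=1e-3)


def test_build_network_mode_selects_resistance_distribution():
    pat = reference_patient()
    for mode, dist in (("rest", REST_R_DISTRIBUTION), ("hyper", STRESS_R_DISTRIBUTION)):
        net = build_network(pat, "pre", mode)
        o = net.branch("LCx").outlet
        total = o.ra + o.ra_micro + o.rv
        assert o.ra / total == pytest.approx(dist[0], rel=1e-9)
        assert o.ra_micro / total == pytest.approx(dist[1], rel=1e-9)


def test_build_network_is_deterministic():
    pat = reference_patient()
    n1 = build_network(pat, "pre", "rest")
    n2 = build_network(pat, "pre", "rest")
    for b1, b2 in zip(n1.branches, n2.branches):
        assert b1.outlet.ra == b2.outlet.ra
        assert np.array_equal(b1.outlet.pim.values, b2.outlet.pim.values)
    assert n1.systemic.rp == n2.systemic.rp


def test_degree_zero_matches_lesion_free_total_resistance():
    from types import SimpleNamespace
    pat = reference_patient()
    free = SimpleNamespace(pre=pat.pre, post=pat.post, lesion_vessel="LAD",
                           stenosis_degree=0.0, stenosis_length=15.0,
                           branch_radii={}, rap=5.0)
    net = build_network(free, "pre", "rest")
    b = net.branch("LAD")
    assert b.stenosis is None
    fluid = net.fluid
    assert chain_resistance(b, fluid) == pytest.approx(
        sum(poiseuille_resistance(s.radius, s.length, fluid) for s in b.chain))


def test_build_network_rejects_unknown_lesion_vessel():
    from types import SimpleNamespace
    pat = reference_patient()
    bad = SimpleNamespace(pre=pat.pre, post=pat.post, lesion_vessel="OM1",
                          stenosis_degree=0.5, stenosis_length=15.0,
                          branch_radii={}, rap=5.0)
    with pytest.raises(ValueError):
        build_network(bad, "pre", "rest")


def test_equal_ostial_areas_make_velocity_ratio_a_flow_ratio():
    """With equal left and right ostial areas, the 3:1 velocity target is
    identically a 3:1 flow split."""
    from coroflow.network import allocate_flows
    pat = reference_patient()
    net = build_network(pat, "pre", "rest")
    for b in net.branches:
        for seg in b.chain:
            seg.radius = 0.2  # force equal ostial areas
    q = allocate_flows(net.branches, 4.0, murray_exponent=3.0,
                       lr_velocity_ratio=3.0)
    q_left = q["LAD"] + q["LCx"]
    assert q_left / q["RCA"] == pytest.approx(3.0, rel=1e-9)
    assert sum(q.values()) == pytest.approx(4.0, abs=1e-12)


def test_ramus_branch_only_for_ramus_lesion():
    pat = reference_patient(lesion_vessel="ramus")
    net = build_network(pat, "pre", "rest")
    assert {b.name for b in net.branches} == {"LAD", "LCx", "RCA", "ramus"}
    pat2 = reference_patient(lesion_vessel="LAD")
    net2 = build_network(pat2, "pre", "rest")
    assert {b.name for b in net2.branches} == {"LAD", "LCx", "RCA"}
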