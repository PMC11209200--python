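import math

import pytest
from hypothesis import given, settings, strategies as st

from nemascreen.fugacity import (
    COMPARTMENTS,
    EvaluativeEnvironment,
    batch_distribute,
    compute_z_values,
    default_environment,
    distribute,
    load_environment,
    round_half_up,
    write_ped_csv,
)
from nemascreen.registry import ClassGroup, CompoundRecord

from conftest import CARVACROL, FLUOPYRAM, OXAMYL

GAS_R = 8.314


def make_record(h=1.0, log_kow=2.0, koc=None, vp=1.0, s=100.0, m=200.0, tm=0.0):
    return CompoundRecord(
        name="probe",
        cas="50-00-0",
        class_group=ClassGroup.TERPENE,
        molar_mass=m,
        melting_point=tm,
        vapour_pressure=vp,
        water_solubility=s,
        log_kow=log_kow,
        henry_constant=h,
        koc=koc,
    )


def brute_force_fractions(record, env):
    """Independent literal-formula evaluation of the Level I distribution."""
    h = record.henry_constant
    koc = record.koc if record.koc is not None else 0.35 * 10 ** record.log_kow
    kow = 10 ** record.log_kow
    t = env.temperature
    tm_k = record.melting_point + 273.15
    f_ratio = math.exp(6.79 * (1 - tm_k / t)) if tm_k > t else 1.0
    p_l = record.vapour_pressure / f_ratio
    z = {
        "air": 1 / (GAS_R * t),
        "water": 1 / h,
        "soil": (1 / h) * (env.solids_density["soil"] / 1000) * env.organic_carbon_fraction["soil"] * koc,
        "sediment": (1 / h)
        * (env.solids_density["sediment"] / 1000)
        * env.organic_carbon_fraction["sediment"]
        * koc,
        "suspended_particles": (1 / h)
        * (env.solids_density["suspended_particles"] / 1000)
        * env.organic_carbon_fraction["suspended_particles"]
        * koc,
        "biota": (1 / h) * (env.solids_density["biota"] / 1000) * env.lipid_fraction_biota * kow,
        "aerosols": (1 / (GAS_R * t)) * 6e6 / p_l if p_l > 0 else 0.0,
    }
    zv = {c: z[c] * env.volumes[c] for c in z}
    total = sum(zv.values())
    return {c: 100 * zv[c] / total for c in zv}


class TestDefaultEnvironment:
    def test_standard_world(self, env):
        assert env.volumes["air"] == 1e14
        assert env.volumes["water"] == 2e11
        assert env.volumes["soil"] == 9e9
        assert env.emission_mass_kg == 100_000
        assert env.temperature == 298.15
        assert env.organic_carbon_fraction == {
            "soil": 0.02,
            "sediment": 0.04,
            "suspended_particles": 0.2,
        }

    def test_version_stamped(self, env):
        assert env.version

    def test_override_from_yaml(self, tmp_path):
        path = tmp_path / "env.yaml"
        path.write_text("temperature: 288.15\nvolumes:\n  water: 1.0e+12\n")
        env = load_environment(path)
        assert env.temperature == 288.15
        assert env.volumes["water"] == 1e12
        assert env.volumes["air"] == 1e14  # untouched defaults survive

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            default_environment().replace(organic_carbon_fraction={"soil": 1.5})


class TestZValues:
    def test_z_air_closed_form(self, dataset, env):
        zset = compute_z_values(dataset.compound(FLUOPYRAM), env)
        assert zset.z["air"] == pytest.approx(4.034e-4, rel=1e-3)

    def test_z_water_reciprocal_h(self, dataset, env):
        zset = compute_z_values(dataset.compound(FLUOPYRAM), env)
        assert zset.z["water"] == pytest.approx(1 / 2.98e-5, rel=1e-12)

    def test_large_h_limit(self, env):
        z_small = compute_z_values(make_record(h=1e6), env)
        z_ref = compute_z_values(make_record(h=1.0), env)
        assert z_small.z["water"] < 1e-5
        assert z_small.z["air"] == z_ref.z["air"]

    def test_nonpositive_h_rejected(self, env):
        record = make_record(h=1.0)
        record.henry_constant = None
        record.vapour_pressure = 0.0
        with pytest.raises(ValueError):
            compute_z_values(record, env)


class TestDistribute:
    def test_fluopyram_matches_published(self, dataset, env):
        result = distribute(dataset.compound(FLUOPYRAM), env)
        rounded = result.rounded()
        assert rounded["soil"] == 59.3
        assert rounded["water"] == 39.3
        assert rounded["sediment"] == 1.3

    def test_carvacrol_matches_published(self, dataset, env):
        rounded = distribute(dataset.compound(CARVACROL), env).rounded()
        assert rounded == {
            "aerosols": 0.0,
            "air": 2.7,
            "biota": 0.0,
            "sediment": 1.3,
            "soil": 59.2,
            "suspended_particles": 0.0,
            "water": 36.7,
        }

    def test_fugacity_positive_and_consistent(self, dataset, env):
        result = distribute(dataset.compound(FLUOPYRAM), env)
        assert result.fugacity_pa > 0
        assert result.total_moles == pytest.approx(1e8 / 396.76, rel=1e-12)

    def test_constructed_air_water_symmetry(self, env):
        # Koc = 0, Kow tiny, H = RT * V_water/V_air makes Z_air V_air == Z_water V_water
        h = GAS_R * env.temperature * env.volumes["water"] / env.volumes["air"]
        record = make_record(h=h, koc=1e-30, log_kow=-30, vp=0.0)
        fractions = distribute(record, env).mass_fraction_percent
        assert fractions["air"] == pytest.approx(fractions["water"], rel=1e-9)

    def test_two_compartment_closed_form(self, env):
        reduced = env.replace(
            volumes={c: 0.0 for c in COMPARTMENTS if c not in ("air", "water")}
        )
        record = make_record(h=0.5, koc=100.0, vp=1.0)
        fractions = distribute(record, reduced).mass_fraction_percent
        va, vw, h, t = 1e14, 2e11, 0.5, 298.15
        expected_air = 100 * (va * h / (GAS_R * t)) / (va * h / (GAS_R * t) + vw)
        assert fractions["air"] == pytest.approx(expected_air, rel=1e-12)
        assert fractions["water"] == pytest.approx(100 - expected_air, rel=1e-9)

    def test_discrepant_h_flagged(self, dataset, env):
        result = distribute(dataset.compound("589-98-0"), env)  # 3-octanol
        assert "henry_discrepant" in result.flags


h_strategy = st.floats(1e-8, 1e4)
koc_strategy = st.floats(1e-4, 1e6)
log_kow_strategy = st.floats(-3, 7)
vp_strategy = st.floats(1e-8, 1e4)
tm_strategy = st.floats(-100, 300)


class TestInvariants:
    @settings(max_examples=150, deadline=None)
    @given(h=h_strategy, koc=koc_strategy, log_kow=log_kow_strategy, vp=vp_strategy, tm=tm_strategy)
    def test_conservation(self, h, koc, log_kow, vp, tm):
        record = make_record(h=h, koc=koc, log_kow=log_kow, vp=vp, tm=tm)
        fractions = distribute(record, default_environment()).mass_fraction_percent
        assert sum(fractions.values()) == pytest.approx(100.0, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(h=h_strategy, koc=koc_strategy, log_kow=log_kow_strategy)
    def test_emission_invariance(self, h, koc, log_kow):
        record = make_record(h=h, koc=koc, log_kow=log_kow)
        big = distribute(record, default_environment().replace(emission_mass_kg=1e5))
        small = distribute(record, default_environment().replace(emission_mass_kg=1.0))
        for c in COMPARTMENTS:
            assert big.mass_fraction_percent[c] == pytest.approx(
                small.mass_fraction_percent[c], rel=1e-12
            )
        assert big.fugacity_pa == pytest.approx(1e5 * small.fugacity_pa, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(h=st.floats(1e-6, 1e2), koc=st.floats(1e-2, 1e4))
    def test_h_monotonicity(self, h, koc):
        env = default_environment()
        lo = distribute(make_record(h=h, koc=koc), env).mass_fraction_percent
        hi = distribute(make_record(h=3 * h, koc=koc), env).mass_fraction_percent
        assert hi["air"] > lo["air"]
        assert hi["water"] < lo["water"]

    @settings(max_examples=50, deadline=None)
    @given(h=st.floats(1e-6, 1e2), koc=st.floats(1e-2, 1e4))
    def test_koc_monotonicity(self, h, koc):
        env = default_environment()
        sorbed = lambda p: p["soil"] + p["sediment"] + p["suspended_particles"]
        lo = distribute(make_record(h=h, koc=koc), env).mass_fraction_percent
        hi = distribute(make_record(h=h, koc=3 * koc), env).mass_fraction_percent
        assert sorbed(hi) > sorbed(lo)

    def test_vanishing_partitioning_drives_water_to_100(self):
        record = make_record(h=1e-12, koc=1e-30, log_kow=-30, vp=0.0)
        fractions = distribute(record, default_environment()).mass_fraction_percent
        assert fractions["water"] == pytest.approx(100.0, abs=1e-3)

    @settings(max_examples=200, deadline=None)
    @given(h=h_strategy, koc=koc_strategy, log_kow=log_kow_strategy, vp=vp_strategy, tm=tm_strategy)
    def test_brute_force_oracle_agreement(self, h, koc, log_kow, vp, tm):
        record = make_record(h=h, koc=koc, log_kow=log_kow, vp=vp, tm=tm)
        env = default_environment()
        computed = distribute(record, env).mass_fraction_percent
        expected = brute_force_fractions(record, env)
        for c in COMPARTMENTS:
            assert computed[c] == pytest.approx(expected[c], rel=1e-12, abs=1e-300)


class TestBatch:
    def test_fixture_rows_sum_to_100(self, dataset, env):
        results = batch_distribute(dataset.compounds, env)
        assert len(results) == 25
        for result in results:
            assert sum(result.mass_fraction_percent.values()) == pytest.approx(100, rel=1e-9)

    def test_order_preserved(self, dataset, env):
        results = batch_distribute(dataset.compounds, env)
        assert [r.compound_cas for r in results] == [c.cas for c in dataset.compounds]

    def test_empty_input(self, env):
        assert batch_distribute([], env) == []

    def test_non_reconstructable_flagging(self, dataset, env, ped_reference):
        results = batch_distribute(dataset.compounds, env, reference=ped_reference)
        flagged = {r.compound_cas for r in results if "non_reconstructable" in r.flags}
        expected = {
            "318290-98-1",  # fluensulfone
            "693-54-9",  # 2-decanone
            "112-14-1",  # octyl acetate
            "112-12-9",  # 2-undecanone
            "2179-57-9",  # diallyl disulphide
            "2050-87-5",  # diallyl trisulphide
            "6028-61-1",  # dipropyl trisulphide
            "17619-36-2",  # methyl propyl trisulphide
            "100-52-7",  # benzaldehyde
            "512-85-6",  # cis-ascaridole
            "99-49-0",  # carvone
        }
        assert flagged == expected

    def test_per_row_error_collected(self, env):
        good = make_record(h=1.0)
        bad = make_record(h=1.0)
        bad.henry_constant = None
        bad.vapour_pressure = 0.0  # H underivable -> row error, batch continues
        results = batch_distribute([good, bad, good], env)
        assert len(results) == 3
        assert results[1].error is not None and "error" in results[1].flags
        assert results[0].error is None

    def test_csv_writer(self, dataset, env, tmp_path):
        path = tmp_path / "ped.csv"
        write_ped_csv(batch_distribute(dataset.compounds[:3], env), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "cas,name,aerosols,air,biota,sediment,soil,suspended_particles,water,flags"
        assert len(lines) == 4


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(59.25, 1) == 59.3
        assert round_half_up(2.749, 1) == 2.7
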