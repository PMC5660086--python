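"""Site-level SILAC quantitation: weighting, normalization, flags, joins."""

import math
import random

import numpy as np
import pytest

from sumoremnant.quant import (
    DualModRecord,
    SilacMeasurement,
    SiteQuant,
    compare_conditions,
    dual_modification_table,
    flag_changing,
    normalize_ratios,
    quantify_sites,
    site_ratio,
)


def meas(log2_ratio, weight, pep="PEPK", acc="P1", pos=10):
    light = weight / (1 + 2.0**log2_ratio)
    heavy = weight - light
    return SilacMeasurement(pep, acc, pos, heavy, light)


def test_weighted_average_example():
    ms = [meas(1.0, 3e6), meas(2.0, 1e6)]
    assert site_ratio(ms) == pytest.approx(1.25)


def test_single_measurement_is_identity():
    assert site_ratio([meas(0.7, 1e5)]) == pytest.approx(0.7)


def test_site_ratio_matches_brute_force():
    rng = random.Random(5)
    ms = [meas(rng.uniform(-2, 2), rng.uniform(1e4, 1e7)) for _ in range(20)]
    expected = sum(m.weight * m.log2_ratio for m in ms) / sum(m.weight for m in ms)
    assert site_ratio(ms) == pytest.approx(expected)


def test_weight_scale_invariance():
    ms = [meas(1.0, 3e6), meas(-0.5, 1e6), meas(0.2, 5e5)]
    scaled = [SilacMeasurement(m.peptide, m.accession, m.position,
                               m.heavy * 7.3, m.light * 7.3) for m in ms]
    assert site_ratio(scaled) == pytest.approx(site_ratio(ms))


def test_zero_channel_measurements_excluded_and_warned():
    with pytest.warns(UserWarning):
        assert site_ratio([SilacMeasurement("P", "P1", 1, 100.0, 0.0)]) is None
    ok = site_ratio([SilacMeasurement("P", "P1", 1, 100.0, 0.0), meas(1.0, 1e6)])
    assert ok == pytest.approx(1.0)


def test_negative_intensity_rejected():
    with pytest.raises(ValueError):
        SilacMeasurement("P", "P1", 1, -1.0, 10.0)


def test_linear_mode_differs_from_log_mode():
    ms = [meas(0.0, 1e6), meas(2.0, 1e6)]
    log_avg = site_ratio(ms, mode="log2")
    lin_avg = site_ratio(ms, mode="linear")
    assert log_avg == pytest.approx(1.0)
    # linear average of ratios 1 and 4 is 2.5 -> log2(2.5)
    assert lin_avg == pytest.approx(math.log2(2.5), abs=0.2)


def test_normalize_examples():
    assert normalize_ratios({"a": 1, "b": 2, "c": 3}) == {"a": -1, "b": 0, "c": 1}
    centered = {"a": -1.0, "b": 0.0, "c": 1.0}
    assert normalize_ratios(centered) == centered
    rng = random.Random(8)
    rand = {i: rng.gauss(2, 3) for i in range(101)}
    assert abs(np.median(list(normalize_ratios(rand).values()))) < 1e-12
    with pytest.raises(ValueError):
        normalize_ratios({})


def test_flag_changing_hand_oracle():
    # median 0.05, s.d. by hand over {0, 0.1, -0.1, 2.0}
    vals = {"s1": 0.0, "s2": 0.1, "s3": -0.1, "s4": 2.0}
    med = float(np.median(list(vals.values())))
    sd = float(np.std(list(vals.values()), ddof=1))
    flags = flag_changing(vals)
    for k, v in vals.items():
        expected = "unchanged" if abs(v - med) <= sd else ("up" if v > med else "down")
        assert flags[k][0] == expected
    assert flags["s4"][0] == "up"
    assert sum(f[0] != "unchanged" for f in flags.values()) == 1


def test_flag_changing_all_equal_none_flagged():
    flags = flag_changing({"a": 0.3, "b": 0.3, "c": 0.3})
    assert all(f[0] == "unchanged" for f in flags.values())


def test_twofold_flags():
    flags = flag_changing({"up": 1.2, "down": -1.2, "mid": 0.4}, sd_mult=10)
    assert flags["up"][1] == "up"
    assert flags["down"][1] == "down"
    assert flags["mid"][1] == "neither"


def test_single_site_sd_undefined_but_twofold_computed():
    flags = flag_changing({"only": -1.5})
    assert flags["only"] == (None, "down")


def test_compare_conditions():
    assert compare_conditions([0, 0.1, -0.1], [0, 0.1, -0.1])[1] == pytest.approx(1.0)
    t, p = compare_conditions([0, 0.1, -0.1], [3.0, 3.1, 2.9])
    assert p < 0.01
    assert compare_conditions([1.0], [0, 1]) is None
    assert compare_conditions([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


def test_welch_t_matches_closed_form():
    a = [0.1, 0.5, -0.2, 0.3]
    b = [1.1, 0.9, 1.4]
    t, p = compare_conditions(a, b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t_expected = (ma - mb) / math.sqrt(va / len(a) + vb / len(b))
    assert t == pytest.approx(t_expected)


def quant(acc, pos, ratio):
    return SiteQuant(acc, pos, "GlyGly", ratio, 1)


def test_dual_table_examples():
    recs, summary = dual_modification_table([quant("P1", 10, 1.0)],
                                            [quant("P1", 10, -0.5)])
    assert summary["lysines_both"] == 1
    assert summary["proteins_both"] == 1
    (rec,) = recs
    assert rec.sumo_log2_ratio == 1.0 and rec.ub_log2_ratio == -0.5

    recs, summary = dual_modification_table([quant("P1", 10, 1.0)],
                                            [quant("P2", 3, 0.0)])
    assert summary["lysines_both"] == 0
    assert summary["proteins_both"] == 0


def test_dual_table_matches_set_intersection():
    rng = random.Random(13)
    sumo = [quant(f"P{rng.randrange(6)}", rng.randrange(30), rng.gauss(0, 1))
            for _ in range(25)]
    ub = [quant(f"P{rng.randrange(6)}", rng.randrange(30), rng.gauss(0, 1))
          for _ in range(25)]
    sumo = list({q.site_key: q for q in sumo}.values())
    ub = list({q.site_key: q for q in ub}.values())
    recs, summary = dual_modification_table(sumo, ub)
    skeys = {q.site_key for q in sumo}
    ukeys = {q.site_key for q in ub}
    assert summary["lysines_both"] == len(skeys & ukeys)
    assert len(recs) == len(skeys | ukeys)
    assert summary["proteins_both"] == len({k[0] for k in skeys} & {k[0] for k in ukeys})


def test_dual_record_requires_a_ratio():
    with pytest.raises(ValueError):
        DualModRecord("P1", 5)


def test_quantify_sites_pipeline_scale_invariant():
    rng = random.Random(2)
    ms = []
    for i in range(20):
        for _ in range(rng.randrange(1, 4)):
            ms.append(meas(rng.gauss(0, 1), rng.uniform(1e4, 1e6),
                           pep=f"PEP{i}K", acc=f"P{i}", pos=5))
    base = quantify_sites(ms)
    scaled = [SilacMeasurement(m.peptide, m.accession, m.position,
                               m.heavy * 100, m.light * 100) for m in ms]
    again = quantify_sites(scaled)
    for q1, q2 in zip(base, again):
        assert q1.log2_ratio == pytest.approx(q2.log2_ratio, abs=1e-9)
        assert (q1.changing, q1.twofold) == (q2.changing, q2.twofold)
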