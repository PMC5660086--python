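"""PSM post-processing: channel merging, FDR, localization, site collapse."""

import itertools
import math
import random

import numpy as np
import pytest
from scipy import stats

from sumoremnant.chem import Modification, Peptide, default_registry, fragment_ions
from sumoremnant.identify import (
    PSMRecord,
    SiteIdentification,
    SpectrumPeaks,
    collapse_to_sites,
    compare_known,
    fdr_filter,
    localize,
    merge_heavy_light,
)

GG = default_registry["GlyGly"]
HEAVY = default_registry["HeavyK(13C6 15N2)"]


def psm(score, decoy=False, sid=None, **kw):
    return PSMRecord(
        spectrum_id=sid or f"s{random.randrange(10**9)}",
        accession=kw.pop("accession", "P1"),
        peptide=kw.pop("peptide", Peptide("AKGG", ((2, GG),))),
        score=score,
        decoy=decoy,
        **kw,
    )


# ---------------------------------------------------------------------------
# heavy/light merging


def test_merge_decomposes_composite_heavy_k():
    composite = Modification("mass:+122.05713", 122.05713, frozenset("K"))
    rec = psm(5.0, label="H", peptide=Peptide("AKGG", ((2, composite),)))
    (out,) = merge_heavy_light([rec])
    names = sorted(m.name for _, m in out.peptide.modifications)
    assert names == ["GlyGly", "HeavyK(13C6 15N2)"]
    assert all(p == 2 for p, _ in out.peptide.modifications)
    assert not out.flags


def test_merge_passes_light_through():
    rec = psm(5.0, label="L", peptide=Peptide("AKGG", ((2, GG),)))
    (out,) = merge_heavy_light([rec])
    assert out.peptide.modifications == rec.peptide.modifications
    assert out.label == "L"


def test_merge_normalizes_plain_heavy_label():
    lab = Modification("mass:8.0142", 8.0142, frozenset("K"))
    rec = psm(5.0, label="H", peptide=Peptide("AKGG", ((2, lab),)))
    (out,) = merge_heavy_light([rec])
    assert [m.name for _, m in out.peptide.modifications] == ["HeavyK(13C6 15N2)"]


def test_merge_flags_unresolved_masses():
    odd = Modification("mass:50.0", 50.0, frozenset("K"))
    rec = psm(5.0, label="H", peptide=Peptide("AKGG", ((2, odd),)))
    (out,) = merge_heavy_light([rec])
    assert any(f.startswith("unresolved_k_mod") for f in out.flags)
    assert out.peptide.modifications == rec.peptide.modifications


# ---------------------------------------------------------------------------
# FDR


def brute_force_qvalues(scored):
    """All-thresholds scan: for each PSM the minimum FDR over any score cut
    at or below its score (decoys counted before targets at ties)."""
    qs = []
    for s, _ in scored:
        fdrs = []
        for cut, _ in scored:
            if cut > s:
                continue
            nd = sum(1 for t, d in scored if (t > cut or (t == cut)) and d)
            nt = sum(1 for t, d in scored if t > cut and not d) + sum(
                1 for t, d in scored if t == cut and not d
            )
            # emulate decoys-first: at the cut score all decoys counted,
            # all equal-scoring targets counted afterwards
            fdrs.append(nd / max(1, nt))
        qs.append(min(fdrs))
    return qs


def test_fdr_one_percent_example():
    psms = [psm(10.0 - 0.01 * i, sid=f"t{i}") for i in range(100)]
    psms.append(psm(9.999, decoy=True, sid="d0"))
    retained, q = fdr_filter(psms, threshold=0.01)
    assert len(retained) == 100
    assert q[:100].max() == pytest.approx(1 / 100)


def test_no_decoys_all_retained_q_zero():
    psms = [psm(float(i), sid=f"t{i}") for i in range(10)]
    retained, q = fdr_filter(psms, threshold=0.01)
    assert len(retained) == 10
    assert np.all(q == 0)


def test_all_decoys_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        retained, q = fdr_filter([psm(1.0, decoy=True), psm(2.0, decoy=True)])
    assert retained == []


def test_qvalues_match_brute_force_scan():
    rng = random.Random(4)
    scored = [(round(rng.gauss(2, 1), 3), rng.random() < 0.4) for _ in range(60)]
    psms = [psm(s, decoy=d, sid=f"x{i}") for i, (s, d) in enumerate(scored)]
    _, q = fdr_filter(psms)
    expected = brute_force_qvalues(scored)
    assert np.allclose(q, expected)


def test_qvalues_monotone_in_score():
    rng = random.Random(7)
    psms = [psm(rng.gauss(0, 1), decoy=rng.random() < 0.3, sid=f"m{i}")
            for i in range(80)]
    _, q = fdr_filter(psms)
    order = np.argsort([-p.score for p in psms])
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_fdr_order_invariance_and_threshold_monotonicity():
    rng = random.Random(9)
    psms = [psm(rng.gauss(1, 1), decoy=rng.random() < 0.3, sid=f"o{i}")
            for i in range(50)]
    base = {p.spectrum_id for p in fdr_filter(psms, 0.05)[0]}
    shuffled = psms[:]
    rng.shuffle(shuffled)
    assert {p.spectrum_id for p in fdr_filter(shuffled, 0.05)[0]} == base
    prev = base
    for thr in (0.02, 0.01, 0.005):
        cur = {p.spectrum_id for p in fdr_filter(psms, thr)[0]}
        assert cur <= prev
        prev = cur


# ---------------------------------------------------------------------------
# localization


def two_k_peptide():
    return Peptide("AKGGAKR", ((2, GG),), 2)


def spectrum_with_all_ions_for(pep_seq, position):
    ions = fragment_ions(Peptide(pep_seq, ((position, GG),)), ("b", "y"), 1)
    mzs = sorted(set(round(m, 4) for _, m in ions))
    return SpectrumPeaks(tuple(mzs), tuple(100.0 for _ in mzs))


def test_single_k_localizes_to_one():
    sp = SpectrumPeaks((500.0,), (1.0,))
    assert localize(sp, Peptide("AKGG", ((2, GG),))) == {2: 1.0}


def test_no_lysine_errors():
    with pytest.raises(ValueError):
        localize(SpectrumPeaks((500.0,), (1.0,)), Peptide("AGGA"))


def test_complete_evidence_gives_confident_placement():
    pep = two_k_peptide()
    probs = localize(spectrum_with_all_ions_for("AKGGAKR", 2), pep)
    assert probs[2] > 0.9
    probs = localize(spectrum_with_all_ions_for("AKGGAKR", 6), pep)
    assert probs[6] > 0.9


def test_no_evidence_is_symmetric():
    probs = localize(SpectrumPeaks((1500.0,), (1.0,)), two_k_peptide())
    assert probs[2] == pytest.approx(0.5)
    assert probs[6] == pytest.approx(0.5)


def test_probabilities_sum_to_one():
    rng = random.Random(3)
    pep = Peptide("KAGKSTKR", ((1, GG),), 2)
    for _ in range(10):
        mzs = sorted({round(rng.uniform(100, 900), 3) for _ in range(30)})
        sp = SpectrumPeaks(tuple(mzs), tuple(rng.uniform(1, 100) for _ in mzs))
        probs = localize(sp, pep)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(probs) == {1, 4, 7}


def test_matches_brute_force_binomial_oracle():
    """Independent oracle on a 2-K peptide: enumerate site-determining ions
    and matches by hand, weight placements by 1/P(X>=k) and normalize."""
    pep = two_k_peptide()
    tol, depth = 0.5, 10
    theo = {}
    for c in (2, 6):
        p = Peptide("AKGGAKR", ((c, GG),), 2)
        theo[c] = {round(mz / tol) for _, mz in fragment_ions(p, ("b", "y"), 1)}
    common = theo[2] & theo[6]
    det = {c: theo[c] - common for c in (2, 6)}

    # spectrum: 3 of placement 2's determining ions present
    some = sorted(det[2])[:3]
    mzs = sorted(k * tol for k in some)
    sp = SpectrumPeaks(tuple(mzs), tuple(10.0 for _ in mzs))

    weights = {}
    for c in (2, 6):
        k = sum(1 for ion in det[c] if ion in {round(m / tol) for m in mzs})
        n = len(det[c])
        weights[c] = 1.0 / stats.binom.sf(k - 1, n, depth / 100.0 * 2 * tol)
    expected = {c: w / sum(weights.values()) for c, w in weights.items()}

    got = localize(sp, pep, GG, tolerance=tol, peak_depth=depth)
    for c in (2, 6):
        assert got[c] == pytest.approx(expected[c], rel=1e-6)


def test_peak_depth_filter_drops_minor_peaks():
    sp = SpectrumPeaks(tuple(float(100 + i) for i in range(20)),
                       tuple(float(i) for i in range(20)))
    top = sp.top_peaks(5)
    assert len(top.mz) == 5
    assert min(top.intensity) == 15.0


# ---------------------------------------------------------------------------
# collapsing and novelty


def localized_psm(sid, acc, start, probs, score=5.0, seq="AKGGAKR"):
    return PSMRecord(
        spectrum_id=sid, accession=acc,
        peptide=Peptide(seq, ((2, GG),)), score=score,
        start=start, site_probs=tuple(probs.items()),
    )


def test_collapse_aggregates_support():
    psms = [
        localized_psm("a", "P1", 10, {2: 0.99}),
        localized_psm("b", "P1", 10, {2: 0.95}, score=7.0),
    ]
    (site,) = collapse_to_sites(psms)
    assert site.accession == "P1"
    assert site.position == 11  # start 10 + local 2 - 1
    assert site.psm_count == 2
    assert site.probability == 0.99
    assert site.best_score == 7.0


def test_collapse_drops_below_threshold():
    assert collapse_to_sites([localized_psm("a", "P1", 10, {2: 0.8})]) == []
    (site,) = collapse_to_sites([localized_psm("a", "P1", 10, {2: 0.8})],
                                localization_threshold=0.7)
    assert site.probability == 0.8


def test_collapse_shared_peptide_flagged_ambiguous():
    sites = collapse_to_sites([localized_psm("a", "P1;P2", 5, {2: 0.99})])
    assert {s.accession for s in sites} == {"P1", "P2"}
    assert all(s.ambiguous for s in sites)


def test_collapse_skips_unmapped_with_warning():
    with pytest.warns(UserWarning):
        out = collapse_to_sites([localized_psm("a", "P1", None, {2: 0.99})])
    assert out == []


def test_collapse_supports_multiple_remnants_per_peptide():
    (s1, s2) = collapse_to_sites(
        [localized_psm("a", "P1", 10, {2: 0.95, 6: 0.93})]
    )
    assert {s1.position, s2.position} == {11, 15}


def site(acc, pos):
    return SiteIdentification(acc, pos, "GlyGly", 1.0, 1, 0.0)


def test_compare_known_examples():
    report = compare_known([site("P1", 10), site("P2", 5)],
                           {"src": [("P1", 10)]})
    assert report["per_source"]["src"]["overlap"] == 1
    assert report["novel"] == 1
    report = compare_known([site("P1", 10)], {"empty": []})
    assert report["novel"] == 1


def test_compare_known_matches_set_algebra():
    rng = random.Random(12)
    ours = [site(f"P{rng.randrange(5)}", rng.randrange(20)) for _ in range(30)]
    known = {
        f"src{j}": {(f"P{rng.randrange(5)}", rng.randrange(20)) for _ in range(15)}
        for j in range(3)
    }
    report = compare_known(ours, known)
    oset = {(s.accession, s.position) for s in ours}
    union = set().union(*known.values())
    assert report["identified"] == len(oset)
    assert report["novel"] == len(oset - union)
    for name, kset in known.items():
        assert report["per_source"][name]["overlap"] == len(oset & kset)
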