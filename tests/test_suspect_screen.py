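"""Suspect screening: characteristic-ion search, isotope and ddMS2
verification, confidence levels and standard confirmation, all scored
against generator ground truth."""

import dataclasses

import pytest

from coformscreen import (
    SpikeSpec,
    SuspectEntry,
    SyntheticRunConfig,
    TheoreticalFragment,
    adduct_mz,
    assign_level,
    confirm_with_standard,
    generate_run,
    match_fragments,
    parse_formula,
    screen_suspects,
    verify_isotope_pattern,
)
from coformscreen.feature_extraction import Feature
from coformscreen.suspect_screen import IdentificationRecord, load_suspect_db


# -- database ---------------------------------------------------------------

DB_CSV = """name,formula,adducts,fragment_formulas,banned_eu,banned_spain,rfd
methylchloroisothiazolinone,C4H4ClNOS,[M+H]+,C3H4NS;C2H2NS,true,false,0.02
lauramide DEA,C16H33NO3,[M+H]+;[M+Na]+,C14H28NO;C4H12NO2,false,false,
aniline,C6H7N,[M+H]+,,true,true,0.007
"""


def test_load_suspect_db(tmp_path):
    p = tmp_path / "db.csv"
    p.write_text(DB_CSV)
    db = load_suspect_db(p)
    assert [e.name for e in db] == [
        "methylchloroisothiazolinone", "lauramide DEA", "aniline"]
    mci, ldea, aniline = db
    assert mci.banned_eu and not mci.banned_spain and mci.rfd == 0.02
    assert ldea.adducts == ("[M+H]+", "[M+Na]+")
    assert [round(f.expected_mz, 5) for f in ldea.fragments] == [226.21654, 106.08626]
    assert aniline.fragments == () and aniline.rfd == 0.007
    (tmp_path / "empty.csv").write_text("name,formula\n")
    with pytest.raises(ValueError):
        load_suspect_db(tmp_path / "empty.csv")


# -- screening --------------------------------------------------------------


def test_screen_finds_planted_suspect(mci_run, blank_run, mci_db):
    run, truth = mci_run
    records = screen_suspects(run, blank_run, mci_db)
    assert len(records) == 1
    rec = records[0]
    assert rec.adduct == "[M+H]+"
    assert abs(rec.mass_error_ppm) <= 5.0
    assert abs(rec.feature.apex_rt - truth.iloc[0]["apex_rt"]) <= 0.1
    assert rec.level == 5  # exact mass only, before evidence upgrades


def test_screen_blank_rule(small_config, mci_spike, mci_db):
    """An analyte present in the blank at the same RT yields no record."""
    from coformscreen import generate_blank
    run, _ = generate_run(small_config, [mci_spike])
    contaminated_blank = generate_blank(small_config, [mci_spike])
    assert screen_suspects(run, contaminated_blank, mci_db) == []


def test_screen_empty_database(mci_run, blank_run):
    run, _ = mci_run
    with pytest.raises(ValueError):
        screen_suspects(run, blank_run, [])


def test_tight_tolerance_drops_jittered_ions(small_config, mci_spike, mci_db):
    """3-ppm planted jitter rarely survives a 0.1-ppm window."""
    cfg = SyntheticRunConfig(**{**small_config.__dict__, "mass_jitter_ppm": 3.0})
    run, _ = generate_run(cfg, [mci_spike])
    loose = screen_suspects(run, None, mci_db, tol_ppm=5.0)
    tight = screen_suspects(run, None, mci_db, tol_ppm=0.1)
    assert len(tight) <= len(loose)


# -- isotope verification ---------------------------------------------------


def test_isotope_verified_for_planted_cl_compound(mci_run, blank_run, mci_db):
    run, _ = mci_run
    rec = screen_suspects(run, blank_run, mci_db)[0]
    rec = verify_isotope_pattern(run, rec)
    assert rec.isotope_verified is True
    assert not rec.rejected


def test_isotope_refuted_for_cl_free_isobar(small_config):
    """A Cl/S-free ion planted at a chlorinated suspect's m/z lacks any
    M+2: the suspect is refuted outright."""
    suspect = SuspectEntry("chloro suspect", parse_formula("C4H4ClNO2"))
    decoy = parse_formula("C7HO3")  # isobaric [M+H]+ within ~2 ppm, no Cl/S
    assert abs(adduct_mz(suspect.formula) - adduct_mz(decoy)) / 134 * 1e6 < 4
    spike = SpikeSpec("decoy", decoy, apex_rt=2.0, apex_intensity=8e5)
    run, _ = generate_run(small_config, [spike])
    records = screen_suspects(run, None, [suspect])
    assert records, "decoy should match by exact mass alone"
    rec = verify_isotope_pattern(run, records[0])
    assert rec.isotope_verified is False
    assert rec.rejected and "M+2" in rec.reject_reason
    assert assign_level(rec).level == 5


def test_intensity_tol_100_reduces_to_presence(mci_run, blank_run, mci_db):
    run, _ = mci_run
    rec = screen_suspects(run, blank_run, mci_db)[0]
    strict = verify_isotope_pattern(run, rec, intensity_tol=30.0)
    loose = verify_isotope_pattern(run, rec, intensity_tol=100.0)
    # presence-only verification can only be more permissive
    assert loose.isotope_verified or not strict.isotope_verified


# -- fragment matching ------------------------------------------------------


def test_fragments_matched_for_planted_suspect(mci_run, blank_run, mci_db):
    run, _ = mci_run
    rec = screen_suspects(run, blank_run, mci_db)[0]
    rec = match_fragments(run, rec)
    assert rec.ms2_available is True
    assert rec.fragments_matched == 2
    assert all(abs(e) < 5.0 for e in rec.fragment_errors_ppm)


def test_zero_fragment_match_rejects(small_config, mci_formula, mci_db):
    """Planted isomer emits wrong fragments: record rejected, stays level 5."""
    wrong = ((TheoreticalFragment.from_formula("C5H9O2"), 0.8),)
    spike = SpikeSpec("isomer", mci_formula, apex_rt=2.0, apex_intensity=8e5,
                      fragments=wrong)
    run, _ = generate_run(small_config, [spike])
    rec = screen_suspects(run, None, mci_db)[0]
    rec = match_fragments(run, rec)
    assert rec.ms2_available is True
    assert rec.fragments_matched == 0
    assert rec.rejected
    assert assign_level(rec).level == 5


def test_no_ms2_events_marks_unavailable(noiseless_config, mci_spike, mci_db):
    cfg = SyntheticRunConfig(**{**noiseless_config.__dict__, "ms2_floor": 1e12})
    run, _ = generate_run(cfg, [mci_spike])
    rec = screen_suspects(run, None, mci_db)[0]
    rec = match_fragments(run, rec)
    assert rec.ms2_available is False
    assert rec.fragments_matched == 0


# -- level assignment -------------------------------------------------------


def _record(mci_db, **kw):
    f = Feature(mz=149.97749, apex_rt=2.0, area=1e6, height=1e5, snr=50, shape=0.99)
    base = IdentificationRecord(entry=mci_db[0], adduct="[M+H]+", feature=f,
                                mass_error_ppm=-2.2)
    return dataclasses.replace(base, **kw)


@pytest.mark.parametrize("kw,expected", [
    (dict(), 5),
    (dict(isotope_verified=True), 4),
    (dict(fragments_matched=2), 3),
    (dict(fragments_matched=2, isotope_verified=True), 2),
    (dict(fragments_matched=2, isotope_verified=True, rt_standard_delta=0.02), 1),
    (dict(fragments_matched=1, isotope_verified=True), 4),   # two-fragment rule
    (dict(fragments_matched=2, rejected=True), 5),
])
def test_level_rule_table(mci_db, kw, expected):
    assert assign_level(_record(mci_db, **kw)).level == expected


def test_levels_monotone_in_evidence(mci_db):
    """Adding evidence never increases the level number."""
    base = assign_level(_record(mci_db)).level
    steps = [
        assign_level(_record(mci_db, isotope_verified=True)).level,
        assign_level(_record(mci_db, isotope_verified=True,
                             fragments_matched=2)).level,
        assign_level(_record(mci_db, isotope_verified=True, fragments_matched=2,
                             rt_standard_delta=0.02)).level,
    ]
    assert all(b <= a for a, b in zip([base] + steps, steps))


def test_two_fragment_rule_never_below_level_4(mci_db):
    for matched in (0, 1):
        for iso in (None, True):
            rec = assign_level(_record(mci_db, fragments_matched=matched,
                                       isotope_verified=iso))
            assert rec.level >= 4


# -- standard confirmation --------------------------------------------------


def test_confirm_with_standard_upgrades(small_config, mci_spike, mci_db):
    run, _ = generate_run(small_config, [mci_spike])
    rec = screen_suspects(run, None, mci_db)[0]
    rec = verify_isotope_pattern(run, rec)
    rec = match_fragments(run, rec)
    rec = assign_level(rec)
    assert rec.level == 2
    # standard planted at a slightly shifted RT, as with real injections
    std_spike = dataclasses.replace(mci_spike, apex_rt=mci_spike.apex_rt + 0.02)
    std_cfg = SyntheticRunConfig(**{**small_config.__dict__, "seed": 77})
    std_run, _ = generate_run(std_cfg, [std_spike], role="solvent-standard")
    confirmed = confirm_with_standard(rec, std_run)
    assert confirmed.level == 1
    assert confirmed.rt_standard_delta == pytest.approx(0.02, abs=0.05)


def test_confirm_threshold_not_met(small_config, mci_spike, mci_db):
    run, _ = generate_run(small_config, [mci_spike])
    rec = screen_suspects(run, None, mci_db)[0]
    rec = assign_level(match_fragments(run, verify_isotope_pattern(run, rec)))
    shifted = dataclasses.replace(mci_spike, apex_rt=mci_spike.apex_rt + 0.15)
    std_run, _ = generate_run(small_config, [shifted], role="solvent-standard")
    confirmed = confirm_with_standard(rec, std_run)
    assert confirmed.level > 1
    assert confirmed.rt_standard_delta > 0.1


def test_confirm_analyte_absent_from_standard(small_config, mci_spike, mci_db,
                                              noiseless_config):
    run, _ = generate_run(small_config, [mci_spike])
    rec = screen_suspects(run, None, mci_db)[0]
    empty_std, _ = generate_run(noiseless_config, [], role="solvent-standard")
    with pytest.raises(ValueError, match="not detected"):
        confirm_with_standard(rec, empty_std)
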