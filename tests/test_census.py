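"""Census I/O, survival-record correction and state classification."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipmviability import census as cs
from ipmviability.errors import CensusValidationError, ConfigurationError

binary_strings = st.text(alphabet="01", min_size=1, max_size=24)


@pytest.mark.parametrize("raw, expected", [
    ("00011101", "00011111"),     # worked example: one dormant year repaired
    ("1111", "1111"),
    ("0101001", "0111111"),
    ("0000", "0000"),
    ("1", "1"),
    ("010", "010"),
])
def test_correct_reincarnation(raw, expected):
    assert cs.correct_reincarnation(raw) == expected


def test_correct_reincarnation_rejects_nonbinary():
    with pytest.raises(CensusValidationError):
        cs.correct_reincarnation("0012")


@given(binary_strings)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_correction_idempotent_and_preserves_endpoints(s):
    c = cs.correct_reincarnation(s)
    assert cs.correct_reincarnation(c) == c
    assert c.find("1") == s.find("1")
    assert c.rfind("1") == s.rfind("1")
    # zeros outside the first..last live span are untouched
    first, last = s.find("1"), s.rfind("1")
    if first != -1:
        assert c[:first] == s[:first] and c[last + 1:] == s[last + 1:]


@given(binary_strings)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_dormant_years_equal_hamming_distance(s):
    c = cs.correct_reincarnation(s)
    flags = cs.score_dormancy(s, c)
    hamming = sum(a != b for a, b in zip(s, c))
    assert flags.count("1") == hamming


@pytest.mark.parametrize("raw, corrected, flags", [
    ("00011101", "00011111", "00000010"),   # dormant in year 7 only
    ("1111", "1111", "0000"),
    ("0100101", "0111111", "0011010"),
])
def test_score_dormancy(raw, corrected, flags):
    assert cs.score_dormancy(raw, corrected) == flags


def test_score_dormancy_length_mismatch():
    with pytest.raises(CensusValidationError):
        cs.score_dormancy("010", "0110")


@pytest.mark.parametrize("alive, diam, dormant, state", [
    (1, 0.0, 0, cs.BOLTER),
    (1, np.nan, 0, cs.BOLTER),
    (1, 12.3, 0, cs.NORMAL),
    (1, np.nan, 1, cs.DORMANT),
    (1, None, 1, cs.DORMANT),
    (0, np.nan, 0, cs.DEAD),
])
def test_classify_state(alive, diam, dormant, state):
    assert cs.classify_state(alive, diam, dormant) == state


def test_classify_state_dormant_requires_alive():
    with pytest.raises(CensusValidationError):
        cs.classify_state(0, np.nan, 1)


@given(st.integers(0, 1), st.one_of(st.none(), st.floats(0, 200)),
       st.integers(0, 1))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_alive_states_partition(alive, diam, dormant):
    if dormant and not alive:
        return
    state = cs.classify_state(alive, diam, dormant)
    if alive:
        assert state in (cs.NORMAL, cs.BOLTER, cs.DORMANT)
    else:
        assert state == cs.DEAD


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

TOY = """population,transect,quadrat,plant_id,year,diameter_mm,survival,fruits
A,T1,Q1,p1,1990,10.5,1,0
A,T1,Q1,p1,1991,NA,1,2
A,T1,Q1,p2,1990,3.0,1,1
"""


def test_read_census_toy(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY)
    df = cs.read_census(path)
    assert len(df) == 3
    assert df["diameter_mm"].isna().sum() == 1
    assert df["year"].dtype.kind == "i"


def test_read_census_duplicate_key(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(TOY + "A,T1,Q1,p2,1990,4.0,1,0\n")
    with pytest.raises(CensusValidationError, match="duplicated"):
        cs.read_census(path)


def test_read_census_negative_diameter(tmp_path):
    path = tmp_path / "neg.csv"
    path.write_text(TOY.replace("3.0", "-3.0"))
    with pytest.raises(CensusValidationError, match="negative"):
        cs.read_census(path)


def test_read_census_dialect_and_missing_column(tmp_path):
    path = tmp_path / "renamed.csv"
    path.write_text(TOY.replace("diameter_mm", "rosette_diam"))
    dialect = {"columns": {"diameter_mm": "rosette_diam"}}
    df = cs.read_census(path, dialect)
    assert "diameter_mm" in df.columns
    with pytest.raises(ConfigurationError):
        cs.read_census(path)          # unmapped column name


def test_roundtrip_write_read(small_census, tmp_path):
    df, _ = small_census
    path = tmp_path / "rt.csv"
    cs.write_census(df, path)
    back = cs.read_census(path)
    pd.testing.assert_frame_equal(
        df.reset_index(drop=True), back, check_dtype=False)


def test_build_histories_rejects_year_gaps():
    df = pd.read_csv(io.StringIO(TOY.replace("1991", "1993")))
    with pytest.raises(CensusValidationError, match="consecutive"):
        cs.build_histories(df)


def test_build_histories_matches_string_correction(small_census):
    """The vectorized reconstruction equals the per-string operations."""
    df, _ = small_census
    for h in cs.build_histories(df)[:500]:
        assert h.corrected_survival == cs.correct_reincarnation(h.raw_survival)
        assert h.dormant_flags == cs.score_dormancy(
            h.raw_survival, h.corrected_survival)


def test_detected_dormancy_matches_truth(small_census):
    """Reconstruction recovers exactly the detectable dormant plant-years.

    A true dormant year is detectable iff the plant was seen aboveground
    both before and after it; the simulator's internal state matrix is the
    oracle.
    """
    df, truth = small_census
    hist = {(h.population, h.plant_id): h for h in cs.build_histories(df)}
    checked = 0
    for pop, mat in truth.true_states.items():
        ids = truth.plant_ids[pop]
        above = (mat == 0) | (mat == 1)       # normal or bolter
        for i, pid in enumerate(ids):
            h = hist.get((pop, pid))
            if h is None:
                continue
            detectable = np.zeros(mat.shape[1], dtype=bool)
            for t in np.flatnonzero(mat[i] == 2):       # truly dormant
                if above[i, :t].any() and above[i, t + 1:].any():
                    detectable[t] = True
            got = np.array([f == "1" for f in h.dormant_flags])
            assert got.tolist() == detectable.tolist()
            checked += detectable.sum()
    assert checked > 0      # the comparison actually exercised dormancy


def test_summarize_cohort_counts():
    df = pd.DataFrame({
        "population": "A", "transect": "T1", "quadrat": "Q1",
        "plant_id": ["p1"] * 3, "year": [1990, 1991, 1992],
        "diameter_mm": [5.0, 6.0, 7.0], "survival": 1, "fruits": 0})
    s = cs.summarize_cohort(cs.build_histories(df))
    assert (s.total_plants, s.n_reincarnates, s.n_bolters) == (1, 0, 0)


def test_summarize_cohort_engineered_reincarnates():
    rows = []
    for k in range(10):
        surv = [1, 0, 1] if k < 3 else [1, 1, 1]     # 3 reincarnates
        for y, sv in zip((1990, 1991, 1992), surv):
            rows.append(dict(population="A", transect="T", quadrat="Q",
                             plant_id=f"p{k}", year=y,
                             diameter_mm=5.0 if sv else np.nan,
                             survival=sv, fruits=np.nan))
    s = cs.summarize_cohort(cs.build_histories(pd.DataFrame(rows)))
    assert s.total_plants == 10
    assert s.n_reincarnates == 3


@pytest.mark.parametrize("count, nq, expected", [
    (300, 30, 10.0), (0, 45, 0.0), (7, 7, 1.0),
])
def test_density_from_counts(count, nq, expected):
    assert cs.density_from_counts(count, nq) == expected


def test_density_series_mean():
    densities = [cs.density_from_counts(c, 10) for c in range(10, 90, 10)]
    assert np.mean(densities) == pytest.approx(4.5)


def test_density_requires_quadrats():
    with pytest.raises(CensusValidationError):
        cs.density_from_counts(10, 0)
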