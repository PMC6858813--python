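import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_max_bonds, oracle_scan, oracle_window_bonds, random_rna
from mircluster.duplex import (
    DEFAULT_ENERGY,
    EnergyModel,
    align_at,
    bond_count,
    fit_bond_energy,
    max_bonds,
    parse_scheme,
    render_scheme,
    reverse_complement,
    scan,
)
from mircluster.errors import BoundsError, ValidationError
from mircluster.seqio import MiRNA, RegionLabel, Transcript


def _tx(seq: str, **kw) -> Transcript:
    kw.setdefault("cds_len", len(seq))
    return Transcript("t", seq, **kw)


@pytest.mark.parametrize(
    "a,b,n",
    [
        ("G", "C", 3),
        ("C", "G", 3),
        ("A", "U", 2),
        ("U", "A", 2),
        ("G", "U", 1),
        ("U", "G", 1),
        ("A", "C", 1),
        ("C", "A", 1),
        ("A", "G", 0),  # purine-purine: no interaction
        ("A", "A", 0),
        ("N", "C", 0),
        ("G", "N", 0),
    ],
)
def test_bond_count_pairing_table(a, b, n):
    assert bond_count(a, b) == n


def test_bond_count_rejects_bad_base():
    with pytest.raises(ValidationError):
        bond_count("X", "A")


@pytest.mark.parametrize(
    "seq,expected",
    [("GGGG", 12), ("AAAA", 8), ("GC" * 11, 66), ("GCAU" * 5 + "CA", 55)],
)
def test_max_bonds_canonical_complement(seq, expected):
    assert max_bonds(MiRNA("m", seq)) == expected


def test_align_perfect_complement():
    # miRNA 5'-UGG-3' against window 5'-CCA-3': C:G=3, C:G=3, A:U=2
    a = align_at(MiRNA("m", "UGG"), _tx("CCA"), 1)
    assert a.bond_vector == (3, 3, 2)
    assert a.bonds_total == 8
    assert a.ratio_pct == 100.0


def test_align_wobble_pair_lowers_ratio():
    # last window base G faces miRNA U: wobble, 1 bond
    a = align_at(MiRNA("m", "UGG"), _tx("CCG"), 1)
    assert a.bond_vector == (3, 3, 1)
    assert a.bonds_total == 7
    assert a.ratio_pct == pytest.approx(87.5)


def test_align_out_of_bounds():
    with pytest.raises(BoundsError):
        align_at(MiRNA("m", "UGG"), _tx("CCA"), 2)


def test_align_matches_bruteforce_recount(rng):
    m = MiRNA("m", random_rna(rng, 22))
    t = _tx(random_rna(rng, 200))
    for start in (1, 50, 179):
        a = align_at(m, t, start)
        window = t.sequence[start - 1 : start - 1 + 22]
        assert a.bonds_total == oracle_window_bonds(m.sequence, window)


def test_ratio_invariant_to_energy_constant(rng):
    m = MiRNA("m", random_rna(rng, 21))
    t = _tx(random_rna(rng, 80))
    a1 = align_at(m, t, 10, EnergyModel(k_hb=2.11))
    a2 = align_at(m, t, 10, EnergyModel(k_hb=5.0))
    assert a1.ratio_pct == pytest.approx(a2.ratio_pct)
    assert a2.delta_g == pytest.approx(a1.delta_g * 5.0 / 2.11)


def test_scan_equals_bruteforce_enumeration(rng):
    """Dual-route check: the vectorized scan against exhaustive per-start
    rescoring, over 100 random miRNA/transcript instances."""
    for _ in range(100):
        L = rng.randint(17, 25)
        m = MiRNA("m", random_rna(rng, L))
        t = _tx(random_rna(rng, rng.randint(L, 1000)))
        threshold = rng.choice([60.0, 75.0, 87.0])
        got = [(a.start, a.bonds_total) for a in scan(m, t, threshold_pct=threshold)]
        assert got == oracle_scan(m.sequence, t.sequence, threshold)


def test_scan_finds_planted_complement(rng):
    m = MiRNA("m", random_rna(rng, 22))
    planted = reverse_complement(m.sequence)
    t = _tx(random_rna(rng, 150) + planted + random_rna(rng, 150))
    hits = scan(m, t, threshold_pct=87.0)
    assert any(a.start == 151 and a.ratio_pct == 100.0 for a in hits)
    assert [(a.start, a.bonds_total) for a in hits] == oracle_scan(
        m.sequence, t.sequence, 87.0
    )


def test_scan_dinucleotide_repeat_yields_stepped_starts():
    """A repeat-matching miRNA hits a run of starts at step 2, one site
    per start (tandem sites are never merged)."""
    m = MiRNA("m", "UG" * 11)
    t = _tx("AAAA" + "CA" * 30 + "AAAA")
    hits = scan(m, t, threshold_pct=100.0)
    starts = [a.start for a in hits]
    assert len(starts) > 1
    assert all(b - a == 2 for a, b in zip(starts, starts[1:]))
    assert all(a.ratio_pct == 100.0 for a in hits)


def test_scan_short_transcript_warns_and_returns_empty():
    m = MiRNA("m", "ACGUACGUACGU")
    t = _tx("ACGU")
    with pytest.warns(UserWarning, match="longer than transcript"):
        assert scan(m, t) == []


def test_scan_rejects_bad_threshold():
    m = MiRNA("m", "ACGU")
    with pytest.raises(ValidationError):
        scan(m, _tx("ACGUACGU"), threshold_pct=120.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_corrupting_a_position_never_raises_ratio(data):
    """Replacing one window base with a lower-bond partner is monotone:
    the ratio cannot increase."""
    seq = data.draw(st.text(alphabet="ACGU", min_size=5, max_size=25))
    m = MiRNA("m", seq)
    window = reverse_complement(seq)
    pos = data.draw(st.integers(0, len(seq) - 1))
    repl = data.draw(st.sampled_from("ACGU"))
    corrupted = window[:pos] + repl + window[pos + 1 :]
    a0 = align_at(m, _tx(window), 1)
    a1 = align_at(m, _tx(corrupted), 1)
    assert a0.ratio_pct == 100.0
    assert a1.ratio_pct <= a0.ratio_pct
    assert 0 <= a1.bonds_total <= max_bonds(m)


def test_perfect_complement_ratio_exactly_100(rng):
    for L in (17, 20, 25):
        seq = random_rna(rng, L)
        a = align_at(MiRNA("m", seq), _tx(reverse_complement(seq)), 1)
        assert a.ratio_pct == 100.0
        assert a.bonds_total == oracle_max_bonds(seq)


def test_n_positions_score_zero_without_failure():
    a = align_at(MiRNA("m", "UGG"), _tx("CNA"), 1)
    assert a.bond_vector == (3, 0, 2)
    assert a.unpaired == 1


def test_scheme_render_and_parse_roundtrip():
    m = MiRNA("ID-test.3p-miR", "UGG")
    a = align_at(m, _tx("CCG"), 1)
    text = render_scheme(a, region=RegionLabel.CDS)
    lines = text.splitlines()
    assert lines[1] == "5'-CCG-3' mRNA"
    assert lines[2].strip() == "||:"  # wobble marked ':'
    assert lines[3] == "3'-GGU-5' miRNA"
    back = parse_scheme(text)
    assert back["start"] == 1
    assert back["ratio_pct"] == pytest.approx(88.0)  # 7/8 rounded
    assert back["mirna_id"] == "ID-test.3p-miR"


def test_fit_bond_energy_recovers_known_constant(rng):
    """Least-squares calibration on synthetic printed values built from a
    known constant recovers it."""
    k_true = 2.11
    obs = []
    for _ in range(8):
        seq = random_rna(rng, rng.randint(18, 25))
        mb = oracle_max_bonds(seq)
        bonds = int(mb * rng.uniform(0.87, 1.0))
        dg = -k_true * bonds
        ratio = 100.0 * bonds / mb
        obs.append((dg, ratio, mb))
    assert fit_bond_energy(obs) == pytest.approx(k_true, rel=1e-9)
    assert DEFAULT_ENERGY.k_hb == pytest.approx(2.11)
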