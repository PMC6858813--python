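import random

import pytest

from mircluster.clusters import (
    cluster_stats,
    find_clusters,
    region_summary,
    render_cluster_diagram,
)
from mircluster.errors import ValidationError
from mircluster.report import round_half_away
from mircluster.seqio import RegionLabel, Transcript
from mircluster.sites import BindingSite


def _site(start, length, mirna="m", dg=-110.0, region=RegionLabel.UTR5):
    return BindingSite(
        mirna_id=mirna,
        gene="G",
        transcript_id="G",
        start=start,
        length=length,
        delta_g=dg,
        ratio_pct=90.0,
        region=region,
    )


def oracle_components(sites):
    """Independent clustering oracle: explicit union-find over the full
    pairwise interval-overlap graph."""
    n = len(sites)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = sites[i], sites[j]
            if a.start <= b.end and b.start <= a.end:  # >=1 shared nt
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(sites[i])
    return sorted(
        (sorted((s.start, s.length) for s in c) for c in comps.values()),
        key=lambda c: c[0],
    )


def test_two_separated_groups_form_two_clusters():
    # starts like the two leader clusters at 184/189/191 and 325/328/334
    sites = [
        _site(184, 24), _site(189, 24, "m2"), _site(191, 23, "m3"),
        _site(325, 25, "m4"), _site(328, 20, "m5"), _site(334, 22, "m6"),
    ]
    c1, c2 = find_clusters(sites)
    assert (c1.n_sites, c2.n_sites) == (3, 3)
    s1, s2 = cluster_stats(c1), cluster_stats(c2)
    assert (s1.total_site_length, s1.span) == (71, 31)
    assert (s2.total_site_length, s2.span) == (67, 32)


def test_disjoint_sites_are_singletons():
    a, b = find_clusters([_site(10, 20), _site(100, 20)])
    assert a.singleton and b.singleton
    stats = cluster_stats(a)
    assert stats.span is None and stats.compaction is None
    assert stats.total_site_length == 20


def test_abutting_sites_do_not_cluster():
    # [10..29] and [30..49]: zero-nt gap, no shared nucleotide
    a, b = find_clusters([_site(10, 20), _site(30, 20)])
    assert a.singleton and b.singleton
    # one shared nucleotide does cluster
    (c,) = find_clusters([_site(10, 20), _site(29, 20)])
    assert c.n_sites == 2


def test_clustering_invariant_to_input_order():
    sites = [_site(s, 23, f"m{i}") for i, s in enumerate((16, 19, 22, 25, 100, 120))]
    ref = [
        [(x.start, x.mirna_id) for x in c.sites] for c in find_clusters(sites)
    ]
    rng = random.Random(7)
    for _ in range(10):
        shuffled = sites[:]
        rng.shuffle(shuffled)
        got = [[(x.start, x.mirna_id) for x in c.sites] for c in find_clusters(shuffled)]
        assert got == ref


def test_clustering_matches_union_find_oracle():
    """Partition + maximality on random instances against an independent
    union-find over the explicit overlap graph."""
    rng = random.Random(20191113)
    for _ in range(50):
        sites = [
            _site(rng.randint(1, 400), rng.randint(17, 25), f"m{i}")
            for i in range(rng.randint(1, 25))
        ]
        got = sorted(
            (sorted((s.start, s.length) for s in c.sites) for c in find_clusters(sites)),
            key=lambda c: c[0],
        )
        assert got == oracle_components(sites)
        assert sum(len(c) for c in got) == len(sites)  # partition


def test_stacked_identical_sites_compaction():
    sites = [_site(50, 22, f"m{i}") for i in range(4)]
    (c,) = find_clusters(sites)
    stats = cluster_stats(c)
    assert stats.total_site_length == 4 * 22
    assert stats.compaction == round_half_away(4 * 22 / c.span, 1)


def test_mean_energy_rounds_half_away_from_zero():
    sites = [_site(10, 22, f"m{i}", dg=d) for i, d in enumerate((-123, -121, -121, -127, -117))]
    stats = cluster_stats(find_clusters(sites)[0])
    assert stats.mean_dg == -122  # -121.8 rounds away from zero


def test_rounding_conventions():
    assert round_half_away(6.75, 1) == 6.8
    assert round_half_away(-121.8) == -122
    assert round_half_away(2.25, 1) == 2.3
    assert round_half_away(-0.5) == -1


def test_region_summary_footprint_and_ratio():
    t = Transcript("t", "A" * 2000, utr5_len=100, cds_len=1402, utr3_len=498)
    # two trailer clusters + totals mirroring a two-cluster region
    sites = [
        _site(1700, 24, "a", region=RegionLabel.UTR3),
        _site(1709, 23, "b", region=RegionLabel.UTR3),
        _site(1800, 23, "c", region=RegionLabel.UTR3),
        _site(1810, 23, "d", region=RegionLabel.UTR3),
    ]
    report = region_summary(find_clusters(sites), t)[RegionLabel.UTR3]
    assert report.n_clusters == 2
    assert report.total_site_length == 93
    # spans: (1709+23)-1700+1=33 and (1810+23)-1800+1=34
    assert report.footprint_nt == 67
    assert report.footprint_fraction == pytest.approx(67 / 498)


def test_region_summary_empty_input():
    assert region_summary([], None) == {}


def test_region_summary_zero_length_region_with_sites_is_error():
    t = Transcript("t", "A" * 100, utr5_len=0, cds_len=100, utr3_len=0)
    sites = [_site(10, 20, region=RegionLabel.UTR5)]
    with pytest.raises(ValidationError):
        region_summary(find_clusters(sites), t)


def test_cluster_diagram_rows_align_to_ruler():
    sites = [_site(16, 24, "mA"), _site(19, 22, "mB"), _site(30, 10, "mC")]
    (c,) = find_clusters(sites)
    text = render_cluster_diagram(c)
    lines = text.splitlines()
    assert len(lines) == 2 + 3  # ruler + extent + one row per site
    assert "mA" in lines[2] and "[16..39]" in lines[2]
    assert lines[2].index("-") < lines[3].index("-")  # later start begins further right
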