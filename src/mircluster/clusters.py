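"""Interval clustering of binding sites and compaction statistics.

Sites whose occupied intervals [start, start+length-1] share at least
one nucleotide — directly or through a chain of overlaps — form a
cluster (a connected component of the interval-overlap graph).  Abutting
sites with a zero-nucleotide gap do not cluster.

The span convention is

    span = max(start + length) - min(start) + 1,

one nucleotide beyond the inclusive union.  This is the convention under
which published cluster sizes (40 nt for a cluster running 16..55, etc.)
are reproduced, and it is applied uniformly.  The compaction ratio,
total summed site length divided by span, quantifies how much the
overlap shrinks the sequence footprint of the sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .report import round_half_away
from .seqio import RegionLabel, Transcript
from .sites import BindingSite


@dataclass(frozen=True)
class Cluster:
    """Maximal set of transitively overlapping sites on one transcript."""

    sites: tuple[BindingSite, ...]  # sorted by start

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValidationError("cluster must contain at least one site")

    @property
    def first(self) -> int:
        return min(s.start for s in self.sites)

    @property
    def last(self) -> int:
        """One nucleotide beyond the rightmost occupied position."""
        return max(s.start + s.length for s in self.sites)

    @property
    def span(self) -> int:
        return self.last - self.first + 1

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_mirnas(self) -> int:
        return len({s.mirna_id for s in self.sites})

    @property
    def singleton(self) -> bool:
        return len(self.sites) == 1


@dataclass(frozen=True)
class ClusterStats:
    """Compaction statistics of one cluster.

    ``span`` and ``compaction`` are None for singleton clusters, which
    have no meaningful extent beyond their own length.
    """

    n_sites: int
    n_mirnas: int
    total_site_length: int
    span: int | None
    compaction: float | None  # total/span, 1 decimal, half-away rounding
    mean_dg: int  # kJ/mole, nearest integer, half-away rounding
    singleton: bool


def find_clusters(sites: Sequence[BindingSite]) -> list[Cluster]:
    """Connected components of the interval-overlap graph.

    Because occupied intervals are contiguous, a single left-to-right
    sweep suffices: a site joins the open component when its start lies
    at or before the component's rightmost occupied nucleotide.
    Deterministic and invariant to input order.
    """
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna_id))
    clusters: list[Cluster] = []
    current = [ordered[0]]
    max_end = ordered[0].end
    for s in ordered[1:]:
        if s.start <= max_end:  # >=1 shared nucleotide
            current.append(s)
            max_end = max(max_end, s.end)
        else:
            clusters.append(Cluster(tuple(current)))
            current = [s]
            max_end = s.end
    clusters.append(Cluster(tuple(current)))
    return clusters


def cluster_stats(c: Cluster) -> ClusterStats:
    """Totals, span, compaction and mean free energy of a cluster."""
    total = sum(s.length for s in c.sites)
    mean_dg = round_half_away(sum(s.delta_g for s in c.sites) / c.n_sites)
    if c.singleton:
        return ClusterStats(
            n_sites=1,
            n_mirnas=1,
            total_site_length=total,
            span=None,
            compaction=None,
            mean_dg=mean_dg,
            singleton=True,
        )
    return ClusterStats(
        n_sites=c.n_sites,
        n_mirnas=c.n_mirnas,
        total_site_length=total,
        span=c.span,
        compaction=round_half_away(total / c.span, 1),
        mean_dg=mean_dg,
        singleton=False,
    )


@dataclass(frozen=True)
class RegionReport:
    """Per-region footprint accounting.

    ``footprint_nt`` sums cluster spans (site length for singletons):
    the stretch of the region actually occupied by binding sites.
    ``compaction`` is total site length over footprint.
    ``footprint_fraction`` is footprint over region length when the
    region length is known.
    """

    region: RegionLabel
    n_clusters: int
    n_sites: int
    n_mirnas: int
    total_site_length: int
    footprint_nt: int
    compaction: float | None
    region_length: int | None
    footprint_fraction: float | None


def region_summary(
    clusters: Iterable[Cluster],
    region_lengths: Transcript | Mapping[RegionLabel, int] | None = None,
) -> dict[RegionLabel, RegionReport]:
    """Aggregate cluster footprints per transcript region."""
    if isinstance(region_lengths, Transcript):
        t = region_lengths
        region_lengths = {
            RegionLabel.UTR5: t.utr5_len,
            RegionLabel.CDS: t.cds_len,
            RegionLabel.UTR3: t.utr3_len,
        }
    by_region: dict[RegionLabel, list[Cluster]] = {}
    for c in clusters:
        regions = {s.region for s in c.sites}
        if len(regions) != 1:
            raise ValidationError("cluster straddles a region boundary label")
        by_region.setdefault(regions.pop(), []).append(c)
    out: dict[RegionLabel, RegionReport] = {}
    for region, cls in by_region.items():
        total = sum(s.length for c in cls for s in c.sites)
        footprint = sum(c.sites[0].length if c.singleton else c.span for c in cls)
        rlen = None if region_lengths is None else int(region_lengths.get(region, 0))
        if rlen == 0 and region_lengths is not None:
            raise ValidationError(f"sites present in zero-length region {region.value}")
        out[region] = RegionReport(
            region=region,
            n_clusters=len(cls),
            n_sites=sum(c.n_sites for c in cls),
            n_mirnas=len({s.mirna_id for c in cls for s in c.sites}),
            total_site_length=total,
            footprint_nt=footprint,
            compaction=round_half_away(total / footprint, 1) if footprint else None,
            region_length=rlen,
            footprint_fraction=(footprint / rlen) if rlen else None,
        )
    return out


def render_cluster_diagram(c: Cluster, width: int = 72) -> str:
    """Monospace diagram: one row per site, dashes over its interval.

    Rows are aligned to a coordinate ruler spanning the cluster.
    """
    first, last_inc = c.first, max(s.end for s in c.sites)
    extent = last_inc - first + 1
    scale = 1 if extent <= width else extent / width
    cols = extent if scale == 1 else width

    def col(pos: int) -> int:
        return min(cols - 1, int((pos - first) / scale))

    ruler = [" "] * cols
    label_l, label_r = str(first), str(last_inc)
    ruler[: len(label_l)] = label_l
    if len(label_r) < cols - len(label_l):
        ruler[cols - len(label_r) :] = label_r
    lines = ["".join(ruler), "=" * cols + "  (cluster extent)"]
    name_w = max(len(s.mirna_id) for s in c.sites) + 2
    for s in sorted(c.sites, key=lambda x: (x.start, x.mirna_id)):
        a, b = col(s.start), col(s.end)
        bar = " " * a + "-" * (b - a + 1)
        lines.append(f"{s.mirna_id:<{name_w}}{bar}  [{s.start}..{s.end}]")
    return "\n".join(lines)
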