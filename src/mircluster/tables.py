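"""Published-style site tables: the TSV dialect, parser, writer, and the
recomputation of every cluster statistic from a table alone.

The dialect mirrors how site tables are printed: one row per miRNA per
(gene, region) block, columns

    gene  rpkm  region  mirna  start_spec  dg_spec  ratio_spec  length

where ``mirna`` may carry a trailing "(n)" multiplicity, and the *_spec
columns hold either a single value or an "a / b" range written with the
obelus separator (e.g. "16 ÷ 25").  Thousands separators and the U+2212
minus sign are accepted on input and never emitted.

Three tables of breast-cancer candidate-gene sites (triple-negative,
luminal A/B and HER2 subtypes) are packaged as fixtures and drive the
statistics recomputation without any sequence data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .clusters import ClusterStats, cluster_stats, find_clusters
from .errors import FormatError
from .report import round_half_away
from .seqio import RegionLabel
from .sites import BindingSite, SiteGroup, expand_group_sites, group_sites

_COLUMNS = ["gene", "rpkm", "region", "mirna", "start_spec", "dg_spec", "ratio_spec", "length"]

#: Identifiers printed with typos in some table rows, mapped to the
#: spelling used in the running text.  Fixture rows keep the verbatim
#: form; this map serves prose cross-reference only.
PROSE_ALIASES = {
    "D00436.3p-miR": "ID00436.3p-miR",
    "D00915.3p-miR": "ID00915.3p-miR",
    "ID0296.3p-miR": "ID00296.3p-miR",
}

_MULT_RE = re.compile(r"^(?P<name>.+?)\s*\((?P<n>\d+)\)$")
_RANGE_SEP = "÷"  # the obelus used in printed ranges


def packaged_table(name: str) -> Path:
    """Path to a packaged site-table fixture.

    Names: ``triple_negative``, ``luminal_ab``, ``her2``.
    """
    ref = resources.files("mircluster").joinpath("data", f"{name}.tsv")
    with resources.as_file(ref) as p:
        return Path(p)


def packaged_table_names() -> list[str]:
    return ["triple_negative", "luminal_ab", "her2"]


def _clean_number(token: str) -> str:
    return token.strip().replace(",", "").replace("−", "-")


def _parse_spec(token: str, *, row: int, column: str) -> tuple[float, float]:
    """Parse "x" or "x / y" into (lo, hi); single values give lo == hi."""
    parts = [p for p in token.split(_RANGE_SEP)]
    try:
        if len(parts) == 1:
            v = float(_clean_number(parts[0]))
            return v, v
        if len(parts) == 2:
            return float(_clean_number(parts[0])), float(_clean_number(parts[1]))
    except ValueError:
        pass
    raise FormatError(f"row {row}: unparseable {column} value {token!r}")


@dataclass(frozen=True)
class TableRow:
    """One printed row: a site group in its (gene, region) block context."""

    gene: str
    rpkm: float | None
    region: RegionLabel
    group: SiteGroup


def parse_table_rows(path: str | Path) -> list[TableRow]:
    """Parse the dialect without expanding multiplicities."""
    rows: list[TableRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise FormatError(f"{path}: expected columns {_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_COLUMNS):
                raise FormatError(f"{path}: row {lineno}: expected {len(_COLUMNS)} fields")
            gene, rpkm_s, region_s, mirna, start_s, dg_s, ratio_s, length_s = fields
            m = _MULT_RE.match(mirna.strip())
            if m:
                name, n = m["name"], int(m["n"])
            else:
                name, n = mirna.strip(), 1
            start_lo, start_hi = _parse_spec(start_s, row=lineno, column="start_spec")
            dg_lo, dg_hi = _parse_spec(dg_s, row=lineno, column="dg_spec")
            ratio_lo, ratio_hi = _parse_spec(ratio_s, row=lineno, column="ratio_spec")
            if n > 1 and start_lo == start_hi:
                raise FormatError(
                    f"{path}: row {lineno}: multiplicity ({n}) with a single start "
                    f"{start_s!r}: no step derivable"
                )
            if n == 1 and start_lo != start_hi:
                raise FormatError(f"{path}: row {lineno}: start range without multiplicity")
            try:
                group = SiteGroup(
                    mirna_id=name,
                    n=n,
                    start_lo=int(start_lo),
                    start_hi=int(start_hi),
                    dg_lo=dg_lo,
                    dg_hi=dg_hi,
                    ratio_lo=ratio_lo,
                    ratio_hi=ratio_hi,
                    length=int(length_s),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: {exc}") from exc
            rpkm = float(_clean_number(rpkm_s)) if rpkm_s.strip() else None
            rows.append(
                TableRow(
                    gene=gene.strip(),
                    rpkm=rpkm,
                    region=RegionLabel.from_string(region_s),
                    group=group,
                )
            )
    return rows


def parse_site_table(path: str | Path) -> list[BindingSite]:
    """Parse a printed-style table and expand every multiplicity.

    Uses lenient arithmetic-progression expansion: a published row whose
    start range is not divisible into integer steps still expands to n
    sites between the printed endpoints.
    """
    sites: list[BindingSite] = []
    for row in parse_table_rows(path):
        sites.extend(
            expand_group_sites(row.group, row.gene, row.region, strict=False)
        )
    return sites


def _format_spec(lo: float, hi: float, *, integer: bool) -> str:
    def fmt(v: float) -> str:
        return str(int(v)) if integer or float(v).is_integer() else str(v)

    if lo == hi:
        return fmt(lo)
    return f"{fmt(lo)} {_RANGE_SEP} {fmt(hi)}"


def write_site_table(rows: Sequence[TableRow], path: str | Path) -> None:
    """Write rows back in the printed dialect (no thousands separators)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            g = r.group
            mirna = g.mirna_id if g.n == 1 else f"{g.mirna_id} ({g.n})"
            if r.rpkm is None:
                rpkm = ""
            elif (r.rpkm * 10).is_integer():
                rpkm = f"{r.rpkm:.1f}"  # printed tables carry one decimal
            else:
                rpkm = repr(r.rpkm)
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        rpkm,
                        r.region.value,
                        mirna,
                        _format_spec(g.start_lo, g.start_hi, integer=True),
                        _format_spec(g.dg_lo, g.dg_hi, integer=True),
                        _format_spec(g.ratio_lo, g.ratio_hi, integer=True),
                        str(g.length),
                    ]
                )
                + "\n"
            )


def rows_from_sites(sites: Sequence[BindingSite], rpkm: float | None = None) -> list[TableRow]:
    """Compress engine output into printed-dialect rows.

    Sites are blocked by (gene, region) and grouped per miRNA with
    :func:`group_sites`; blocks keep first-appearance order.
    """
    blocks: dict[tuple[str, RegionLabel], list[BindingSite]] = {}
    for s in sites:
        blocks.setdefault((s.gene, s.region), []).append(s)
    rows: list[TableRow] = []
    for (gene, region), members in blocks.items():
        per_mirna: dict[tuple[str, int], list[BindingSite]] = {}
        for s in members:
            per_mirna.setdefault((s.mirna_id, s.length), []).append(s)
        for group_sites_list in per_mirna.values():
            for g in group_sites(group_sites_list):
                rows.append(TableRow(gene=gene, rpkm=rpkm, region=region, group=g))
    return rows


# --- prose-statistics recomputation ----------------------------------------


@dataclass(frozen=True)
class BlockReport:
    """All recomputed statistics of one (gene, region) table block."""

    gene: str
    region: RegionLabel
    n_sites: int
    n_mirnas: int
    total_site_length: int
    footprint_nt: int  # sum of cluster spans (length for singletons)
    mean_dg: int  # over every site of the block
    clusters: tuple[ClusterStats, ...]


def recompute_prose(sites: Sequence[BindingSite]) -> dict[tuple[str, str], BlockReport]:
    """Run the full clustering pipeline per (gene, region) block.

    Keys are (gene, region value) pairs; the per-block report carries
    the cluster-by-cluster statistics in left-to-right order.
    """
    blocks: dict[tuple[str, RegionLabel], list[BindingSite]] = {}
    for s in sites:
        blocks.setdefault((s.gene, s.region), []).append(s)
    out: dict[tuple[str, str], BlockReport] = {}
    for (gene, region), members in blocks.items():
        cls = find_clusters(members)
        stats = tuple(cluster_stats(c) for c in cls)
        total = sum(s.length for s in members)
        footprint = sum(
            c.sites[0].length if c.singleton else c.span for c in cls
        )
        mean_dg = round_half_away(sum(s.delta_g for s in members) / len(members))
        out[(gene, region.value)] = BlockReport(
            gene=gene,
            region=region,
            n_sites=len(members),
            n_mirnas=len({s.mirna_id for s in members}),
            total_site_length=total,
            footprint_nt=footprint,
            mean_dg=mean_dg,
            clusters=stats,
        )
    return out


def block_report_text(reports: dict[tuple[str, str], BlockReport]) -> str:
    """Human-readable rendering of :func:`recompute_prose` output."""
    lines = []
    for (gene, region), rep in reports.items():
        lines.append(
            f"{gene} [{region}]: {rep.n_sites} sites / {rep.n_mirnas} miRNAs, "
            f"total {rep.total_site_length} nt, footprint {rep.footprint_nt} nt, "
            f"mean dG {rep.mean_dg} kJ/mole"
        )
        for i, cs in enumerate(rep.clusters, start=1):
            if cs.singleton:
                lines.append(
                    f"  cluster {i}: singleton, {cs.total_site_length} nt, "
                    f"dG {cs.mean_dg} kJ/mole"
                )
            else:
                lines.append(
                    f"  cluster {i}: {cs.n_sites} sites / {cs.n_mirnas} miRNAs, "
                    f"total {cs.total_site_length} nt, span {cs.span} nt, "
                    f"compaction {cs.compaction}, mean dG {cs.mean_dg} kJ/mole"
                )
    return "\n".join(lines)
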