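"""Binding sites and their printed-table representation.

A qualifying duplex alignment becomes a :class:`BindingSite` once it is
localized to a transcript region.  Published site tables compress runs
of equally spaced starts of one miRNA into a single row with an
"(n)" multiplicity and "lo / hi" ranges; :class:`SiteGroup` models that
row, and :func:`expand_group` / :func:`group_sites` convert between the
compressed and expanded forms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .duplex import DuplexAlignment
from .errors import FormatError, ValidationError
from .report import round_half_away
from .seqio import RegionLabel, Transcript, position_region


@dataclass(frozen=True)
class BindingSite:
    """One miRNA binding site on one transcript (1-based start)."""

    mirna_id: str
    gene: str
    transcript_id: str
    start: int
    length: int
    delta_g: float  # kJ/mole, negative
    ratio_pct: float  # percent of maximal binding energy
    region: RegionLabel

    @property
    def end(self) -> int:
        """Last occupied nucleotide (inclusive)."""
        return self.start + self.length - 1


def annotate(a: DuplexAlignment, t: Transcript) -> BindingSite:
    """Attach gene identity and region label to a qualifying alignment.

    A site straddling a region boundary is assigned the region of its
    start nucleotide, so each site carries exactly one label.
    """
    return BindingSite(
        mirna_id=a.mirna_id,
        gene=t.gene,
        transcript_id=t.id,
        start=a.start,
        length=a.length,
        delta_g=a.delta_g,
        ratio_pct=a.ratio_pct,
        region=position_region(t, a.start),
    )


@dataclass(frozen=True)
class SiteGroup:
    """A compressed run of n equally spaced sites of one miRNA.

    ``dg_lo``/``dg_hi`` (and the ratio counterparts) are the printed
    range endpoints; they equal each other when the row prints a single
    value.  For n == 1 the start range collapses to a point.
    """

    mirna_id: str
    n: int
    start_lo: int
    start_hi: int
    dg_lo: float
    dg_hi: float
    ratio_lo: float
    ratio_hi: float
    length: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group multiplicity must be >= 1")
        if self.n == 1 and self.start_lo != self.start_hi:
            raise ValidationError("n == 1 group must have start_lo == start_hi")

    @property
    def dg_mean(self) -> float:
        """Endpoint mean, assigned to every expanded site for averaging."""
        return (self.dg_lo + self.dg_hi) / 2.0

    @property
    def ratio_mean(self) -> float:
        return (self.ratio_lo + self.ratio_hi) / 2.0


def expand_group(g: SiteGroup, *, strict: bool = True) -> list[int]:
    """Expand a group to its n starts in arithmetic progression.

    With ``strict=True`` a span not divisible by n-1 is a format error.
    Lenient mode places intermediate starts at rounded evenly spaced
    positions between the endpoints — the endpoints, count and every
    aggregate statistic (lengths, spans, energies) are unaffected.
    """
    if g.n == 1:
        return [g.start_lo]
    span = g.start_hi - g.start_lo
    if span % (g.n - 1) != 0:
        if strict:
            raise FormatError(
                f"group {g.mirna_id!r}: range {g.start_lo} / {g.start_hi} not an "
                f"integer-step progression of {g.n} starts"
            )
        return [
            g.start_lo + round(i * span / (g.n - 1)) for i in range(g.n)
        ]
    step = span // (g.n - 1)
    return [g.start_lo + i * step for i in range(g.n)]


def expand_group_sites(
    g: SiteGroup,
    gene: str,
    region: RegionLabel,
    *,
    transcript_id: str | None = None,
    strict: bool = True,
) -> list[BindingSite]:
    """Expanded :class:`BindingSite` list for a table row.

    Ranged energies contribute their endpoint mean to every expanded
    site (used only for aggregate statistics, never as a per-site
    energy estimate).
    """
    return [
        BindingSite(
            mirna_id=g.mirna_id,
            gene=gene,
            transcript_id=transcript_id or gene,
            start=s,
            length=g.length,
            delta_g=g.dg_mean,
            ratio_pct=g.ratio_mean,
            region=region,
        )
        for s in expand_group(g, strict=strict)
    ]


def group_sites(sites: Sequence[BindingSite]) -> list[SiteGroup]:
    """Compress sites of one miRNA into maximal equal-step runs.

    Greedy left-to-right: from each unconsumed start, the longest
    arithmetic progression through subsequent starts is taken; ties
    between candidate steps are broken toward the smallest step.
    Inverse of :func:`expand_group` on well-formed groups.
    """
    if not sites:
        return []
    keys = {(s.mirna_id, s.gene, s.region, s.length) for s in sites}
    if len(keys) > 1:
        raise ValidationError("group_sites requires sites sharing miRNA, gene, region, length")
    ordered = sorted(sites, key=lambda s: s.start)
    groups: list[SiteGroup] = []
    while ordered:
        starts = [s.start for s in ordered]
        best_len, best_step = 1, 0
        # candidate steps: differences from the leftmost unconsumed start
        for j in range(1, len(starts)):
            step = starts[j] - starts[0]
            if step <= 0:
                continue
            run, expect = 1, starts[0] + step
            for k in range(1, len(starts)):
                if starts[k] == expect:
                    run += 1
                    expect += step
            if run > best_len or (run == best_len and (best_step == 0 or step < best_step)):
                best_len, best_step = run, step
        members = [ordered[0]]
        if best_len > 1:
            expect = starts[0] + best_step
            for s in ordered[1:]:
                if s.start == expect and len(members) < best_len:
                    members.append(s)
                    expect += best_step
        member_ids = {id(m) for m in members}
        ordered = [s for s in ordered if id(s) not in member_ids]
        first, last = members[0], members[-1]
        groups.append(
            SiteGroup(
                mirna_id=first.mirna_id,
                n=len(members),
                start_lo=first.start,
                start_hi=last.start,
                dg_lo=first.delta_g,
                dg_hi=last.delta_g,
                ratio_lo=first.ratio_pct,
                ratio_hi=last.ratio_pct,
                length=first.length,
            )
        )
    return groups


# --- engine site-list TSV ---------------------------------------------------

_SITE_COLUMNS = ["gene", "region", "mirna_id", "start", "length", "delta_g", "ratio_pct"]


def write_site_tsv(sites: Iterable[BindingSite], path: str | Path) -> None:
    """Write one row per site (no multiplicity compression at this layer)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.gene,
                        s.region.value,
                        s.mirna_id,
                        str(s.start),
                        str(s.length),
                        str(round_half_away(s.delta_g)),
                        str(round_half_away(s.ratio_pct)),
                    ]
                )
                + "\n"
            )


def read_site_tsv(path: str | Path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SITE_COLUMNS:
            raise FormatError(f"{path}: expected columns {_SITE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_SITE_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: expected {len(_SITE_COLUMNS)} fields")
            gene, region, mid, start, length, dg, ratio = fields
            sites.append(
                BindingSite(
                    mirna_id=mid,
                    gene=gene,
                    transcript_id=gene,
                    start=int(start),
                    length=int(length),
                    delta_g=float(dg),
                    ratio_pct=float(ratio),
                    region=RegionLabel.from_string(region),
                )
            )
    return sites
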