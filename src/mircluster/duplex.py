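"""Hydrogen-bond scoring of gapless antiparallel miRNA-mRNA duplexes.

The model counts hydrogen bonds per base pair — G-C: 3, A-U: 2, and the
non-canonical wobble pairs G-U and A-C: 1 each; every other combination
(and any pair involving N) contributes 0.  The hybridization free energy
is a linear function of the bond total,

    dG  = -k_hb * (total hydrogen bonds)          [kJ/mole]
    dGm = -k_hb * max_bonds(miRNA)                [perfect complement]

and a transcript window is a candidate binding site when the fraction of
the maximal binding energy achieved, 100*dG/dGm, reaches a threshold
(87% by default).  Because the energy is linear in the bond count the
ratio is independent of k_hb; k_hb only sets the kJ/mole scale of
reported energies.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ValidationError
from .seqio import MiRNA, RegionLabel, Transcript

#: Hydrogen bonds per ordered (miRNA base, mRNA base) pair.
PAIRING_TABLE: dict[tuple[str, str], int] = {}
for _a, _b, _n in [("G", "C", 3), ("A", "U", 2), ("G", "U", 1), ("A", "C", 1)]:
    PAIRING_TABLE[(_a, _b)] = _n
    PAIRING_TABLE[(_b, _a)] = _n

#: Bonds each miRNA base contributes opposite its canonical complement.
CANONICAL_BONDS = {"A": 2, "U": 2, "G": 3, "C": 3, "N": 0}

_ALPHABET = "ACGUN"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}

# 5x5 bond matrix for the vectorized scan.
_BOND_MATRIX = np.zeros((5, 5), dtype=np.int32)
for (_a, _b), _n in PAIRING_TABLE.items():
    _BOND_MATRIX[_INDEX[_a], _INDEX[_b]] = _n

#: RNA complement used to build perfect-complement windows (N -> N).
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


def reverse_complement(seq: str) -> str:
    """Canonical reverse complement in the RNA alphabet."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def bond_count(mi_base: str, m_base: str) -> int:
    """Hydrogen bonds formed between a miRNA base and an mRNA base."""
    for b in (mi_base, m_base):
        if b not in _INDEX:
            raise ValidationError(f"base {b!r} outside alphabet {_ALPHABET}")
    return PAIRING_TABLE.get((mi_base, m_base), 0)


def max_bonds(m: MiRNA | str) -> int:
    """Bond total of the miRNA paired with its exact canonical complement."""
    seq = m.sequence if isinstance(m, MiRNA) else m
    return sum(CANONICAL_BONDS[b] for b in seq)


@dataclass(frozen=True)
class EnergyModel:
    """Linear bond-count energy model.

    k_hb is the energy magnitude per hydrogen bond in kJ/mole.  The
    default 2.11 was calibrated by least squares against published
    per-site energies of miRBase miRNAs whose sequences (hence bond
    totals) are known.
    """

    k_hb: float = 2.11

    def __post_init__(self) -> None:
        if self.k_hb <= 0:
            raise ValidationError("k_hb must be positive")

    def delta_g(self, bonds: int) -> float:
        return -self.k_hb * bonds


DEFAULT_ENERGY = EnergyModel()


@dataclass(frozen=True)
class DuplexAlignment:
    """A scored gapless duplex at one transcript start.

    ``bond_vector`` is ordered along the mRNA window 5'->3'; position i
    of the window faces miRNA position L-i (the miRNA runs 3'->5'
    underneath the mRNA).
    """

    mirna_id: str
    transcript_id: str
    start: int  # 1-based on the transcript
    mirna_seq: str
    window_seq: str
    bond_vector: tuple[int, ...]
    max_bonds: int
    delta_g: float
    delta_g_max: float

    @property
    def length(self) -> int:
        return len(self.mirna_seq)

    @property
    def bonds_total(self) -> int:
        return sum(self.bond_vector)

    @property
    def ratio_pct(self) -> float:
        # computed from integer bond counts so a perfect complement is
        # exactly 100.0 regardless of k_hb floating-point effects
        return 100.0 * self.bonds_total / self.max_bonds

    @property
    def unpaired(self) -> int:
        return sum(1 for b in self.bond_vector if b == 0)


def align_at(
    m: MiRNA,
    t: Transcript,
    start: int,
    em: EnergyModel = DEFAULT_ENERGY,
) -> DuplexAlignment:
    """Score the duplex of ``m`` against the transcript window at ``start``.

    The pairing is gapless and antiparallel: transcript positions
    start..start+L-1 (5'->3') face miRNA positions L..1.  Unpaired (0
    bond) positions stay in register; bulges are not modeled.
    """
    L = m.length
    if start < 1 or start + L - 1 > t.length:
        raise BoundsError(
            f"window [{start}, {start + L - 1}] outside transcript "
            f"{t.id!r} of length {t.length}"
        )
    window = t.sequence[start - 1 : start - 1 + L]
    mi_rev = m.sequence[::-1]
    vec = tuple(PAIRING_TABLE.get((mi_rev[i], window[i]), 0) for i in range(L))
    mb = max_bonds(m)
    return DuplexAlignment(
        mirna_id=m.id,
        transcript_id=t.id,
        start=start,
        mirna_seq=m.sequence,
        window_seq=window,
        bond_vector=vec,
        max_bonds=mb,
        delta_g=em.delta_g(sum(vec)),
        delta_g_max=em.delta_g(mb),
    )


def scan(
    m: MiRNA,
    t: Transcript,
    threshold_pct: float = 87.0,
    em: EnergyModel = DEFAULT_ENERGY,
) -> list[DuplexAlignment]:
    """All starts whose duplex reaches ``threshold_pct`` of maximal energy.

    Every qualifying start is reported separately — a run of tandem
    repeats yields one site per start, never a merged interval.  Output
    is sorted by ascending start.  The unrounded ratio is compared
    against the threshold.
    """
    if not 0 < threshold_pct <= 100:
        raise ValidationError(f"threshold_pct must be in (0, 100], got {threshold_pct}")
    L = m.length
    n = t.length - L + 1
    if n <= 0:
        warnings.warn(
            f"miRNA {m.id!r} ({L} nt) longer than transcript {t.id!r} ({t.length} nt)",
            stacklevel=2,
        )
        return []
    tcodes = np.fromiter((_INDEX[b] for b in t.sequence), dtype=np.int8, count=t.length)
    mi_rev = m.sequence[::-1]
    totals = np.zeros(n, dtype=np.int32)
    for i, base in enumerate(mi_rev):
        totals += _BOND_MATRIX[_INDEX[base], tcodes[i : i + n]]
    mb = max_bonds(m)
    # integer comparison: 100*bonds >= threshold*max_bonds, robust to float ties
    hits = np.nonzero(100.0 * totals >= threshold_pct * mb - 1e-9)[0]
    return [align_at(m, t, int(s) + 1, em) for s in hits]


# --- interaction-scheme rendering ------------------------------------------

_MARKER = {3: "|", 2: "|", 1: ":", 0: " "}

_HEADER_RE = re.compile(
    r"^(?P<id>\S.*?) \| (?P<region>[^|]+) \| start (?P<start>\d+) \| "
    r"dG (?P<dg>-?\d+(?:\.\d+)?) kJ/mole \| dG/dGm (?P<ratio>\d+(?:\.\d+)?)% \| "
    r"(?P<len>\d+) nt$"
)


def render_scheme(a: DuplexAlignment, region: RegionLabel | None = None) -> str:
    """Render the duplex as a monospace interaction scheme.

    Header line with identity and energies, then the mRNA window 5'->3',
    a marker line ('|' canonical pair, ':' one-bond wobble pair, space
    unpaired), and the miRNA 3'->5' beneath it.
    """
    from .report import round_half_away  # local import to avoid cycle

    markers = "".join(_MARKER[b] for b in a.bond_vector)
    header = (
        f"{a.mirna_id} | {region.value if region else 'n/a'} | start {a.start} | "
        f"dG {round_half_away(a.delta_g):d} kJ/mole | "
        f"dG/dGm {round_half_away(a.ratio_pct):d}% | {a.length} nt"
    )
    return "\n".join(
        [
            header,
            f"5'-{a.window_seq}-3' mRNA",
            f"   {markers}",
            f"3'-{a.mirna_seq[::-1]}-5' miRNA",
        ]
    )


def parse_scheme(text: str) -> dict:
    """Recover (mirna_id, region, start, delta_g, ratio_pct, length) from a scheme."""
    header = text.strip().splitlines()[0]
    match = _HEADER_RE.match(header)
    if match is None:
        raise ValueError(f"unparseable scheme header: {header!r}")
    return {
        "mirna_id": match["id"],
        "region": match["region"].strip(),
        "start": int(match["start"]),
        "delta_g": float(match["dg"]),
        "ratio_pct": float(match["ratio"]),
        "length": int(match["len"]),
    }


def fit_bond_energy(observations: list[tuple[float, float, int]]) -> float:
    """Least-squares estimate of k_hb from published per-site values.

    Each observation is (printed delta_g in kJ/mole, printed ratio in
    percent, max_bonds of the miRNA).  Since dGm = dG/(ratio/100) and
    |dGm| = k_hb * max_bonds, k_hb is fit through the origin:
    k = sum(|dGm_i| * b_i) / sum(b_i^2).
    """
    if not observations:
        raise ValueError("no observations")
    num = 0.0
    den = 0.0
    for dg, ratio, mb in observations:
        if ratio <= 0 or mb <= 0:
            raise ValidationError("ratio and max_bonds must be positive")
        dgm = abs(dg) / (ratio / 100.0)
        num += dgm * mb
        den += mb * mb
    return num / den
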