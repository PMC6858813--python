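"""Seeded synthetic fixtures: transcripts with planted binding sites.

The generator emulates the site structures seen in real scans — exact
complements, sites weakened by wobble (G-U / A-C) pairs or outright
mismatches, and tandem runs of equally spaced sites arising from
short-period sequence repeats — on an i.i.d. random background.  Every
plant carries an a-priori expected bond total and energy ratio, so
recovery tests can check the scanner against ground truth without
re-deriving anything from the generated sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .duplex import CANONICAL_BONDS, max_bonds, reverse_complement
from .errors import ValidationError
from .seqio import MiRNA, Origin, RegionInfo, Transcript, write_fasta, write_regions

_BASES = "ACGU"

#: mRNA substitution turning a canonical pair into the 1-bond wobble
#: pair, keyed by the miRNA base: G-C -> G-U, C-G -> C-A, A-U -> A-C,
#: U-A -> U-G.
_WOBBLE_SUB = {"G": "U", "C": "A", "A": "C", "U": "G"}

#: mRNA substitution yielding 0 bonds opposite the given miRNA base.
_MISMATCH_SUB = {"G": "A", "C": "C", "A": "A", "U": "U"}


@dataclass(frozen=True)
class PlantSpec:
    """One planted site (or tandem run) in a transcript.

    ``n_wobble`` positions of the perfect-complement window are turned
    into wobble pairs and ``n_mismatch`` into 0-bond mismatches, at
    distinct positions.  ``tandem > 1`` plants a run of equally spaced
    perfect sites; this requires the miRNA sequence to be periodic with
    period ``step`` so that every shifted window is also an exact
    complement (how tandem sites arise in real transcripts).
    """

    mirna_id: str
    position: int  # 1-based start of the (first) site
    n_mismatch: int = 0
    n_wobble: int = 0
    tandem: int = 1
    step: int = 0


@dataclass(frozen=True)
class PlantTruth:
    mirna_id: str
    start: int
    expected_bonds: int
    expected_ratio_pct: float


@dataclass(frozen=True)
class SynthTruth:
    plants: tuple[PlantTruth, ...]

    def to_json(self, path: str | Path) -> None:
        payload = [vars(p) for p in self.plants]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(PlantTruth(**p) for p in payload))


@dataclass(frozen=True)
class SynthConfig:
    """Study-like defaults: a 1 kb transcript with leader/coding/trailer
    proportions and 17-25 nt miRNAs, uniform base composition."""

    utr5_len: int = 150
    cds_len: int = 600
    utr3_len: int = 250
    gc_content: float = 0.5
    mirna_lengths: tuple[int, ...] = (22, 23, 24, 21, 25)
    plants: tuple[PlantSpec, ...] = (
        PlantSpec("syn-mir-1", position=31),  # exact complement in 5'UTR
        PlantSpec("syn-mir-2", position=201, n_wobble=2),  # weakened, CDS
        PlantSpec("syn-mir-3", position=401, n_mismatch=1, n_wobble=1),
        PlantSpec("syn-mir-4", position=801, tandem=6, step=2),  # dinucleotide repeat
        PlantSpec("syn-mir-5", position=901, tandem=4, step=3),  # trinucleotide repeat
    )

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


@dataclass(frozen=True)
class SynthBundle:
    mirnas: tuple[MiRNA, ...]
    transcript: Transcript
    truth: SynthTruth
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirnas": out / "mirnas.fasta",
            "transcripts": out / "transcripts.fasta",
            "regions": out / "regions.tsv",
            "truth": out / "truth.json",
        }
        write_fasta(self.mirnas, paths["mirnas"])
        write_fasta([self.transcript], paths["transcripts"])
        t = self.transcript
        write_regions(
            {t.id: RegionInfo(t.utr5_len, t.cds_len, t.utr3_len, t.rpkm)},
            paths["regions"],
        )
        self.truth.to_json(paths["truth"])
        return paths


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=n, p=p))


def _periodic_mirna(rng: np.random.Generator, length: int, period: int, gc: float) -> str:
    unit = _random_seq(rng, period, gc)
    return (unit * (length // period + 1))[:length]


def generate(config: SynthConfig = SynthConfig(), seed: int = 0) -> SynthBundle:
    """Deterministically generate miRNAs, one transcript, and ground truth.

    Planted windows are the canonical reverse complement of their miRNA
    with exactly the requested corruptions; corruption positions are
    drawn from the single seeded RNG stream, so identical (config, seed)
    give identical sequences byte for byte.
    """
    rng = np.random.default_rng(seed)
    if len(config.mirna_lengths) < len(config.plants):
        raise ValidationError("need one miRNA length per plant")

    mirnas: list[MiRNA] = []
    specs = list(config.plants)
    for spec, L in zip(specs, config.mirna_lengths):
        if spec.tandem > 1:
            if spec.step < 1:
                raise ValidationError(f"plant {spec.mirna_id!r}: tandem requires step >= 1")
            if spec.n_wobble or spec.n_mismatch:
                raise ValidationError(
                    f"plant {spec.mirna_id!r}: tandem runs are planted uncorrupted"
                )
            seq = _periodic_mirna(rng, L, spec.step, config.gc_content)
        else:
            seq = _random_seq(rng, L, config.gc_content)
        mirnas.append(MiRNA(id=spec.mirna_id, sequence=seq, origin=Origin.UNKNOWN))

    background = list(_random_seq(rng, config.transcript_length, config.gc_content))
    truths: list[PlantTruth] = []
    occupied: list[tuple[int, int]] = []
    for spec, m in zip(specs, mirnas):
        L = m.length
        window = list(reverse_complement(m.sequence))
        mb = max_bonds(m)
        # corrupt distinct positions; record expected bond loss a priori
        n_corrupt = spec.n_wobble + spec.n_mismatch
        if n_corrupt > L:
            raise ValidationError(f"plant {spec.mirna_id!r}: more corruptions than positions")
        pos = rng.choice(L, size=n_corrupt, replace=False) if n_corrupt else []
        loss = 0
        for idx, p in enumerate(pos):
            # window position p faces miRNA position L-1-p (antiparallel)
            mi_base = m.sequence[L - 1 - int(p)]
            if idx < spec.n_wobble:
                window[int(p)] = _WOBBLE_SUB[mi_base]
                loss += CANONICAL_BONDS[mi_base] - 1
            else:
                window[int(p)] = _MISMATCH_SUB[mi_base]
                loss += CANONICAL_BONDS[mi_base]
        expected = mb - loss
        span_len = L + (spec.tandem - 1) * spec.step
        lo, hi = spec.position, spec.position + span_len - 1
        if lo < 1 or hi > config.transcript_length:
            raise ValidationError(f"plant {spec.mirna_id!r} exceeds transcript bounds")
        for a, b in occupied:
            if lo <= b and a <= hi:
                raise ValidationError(f"plant {spec.mirna_id!r} overlaps another plant")
        occupied.append((lo, hi))
        if spec.tandem > 1:
            # periodic extension keeps every shifted window a perfect complement
            unit = window[: spec.step]
            stretch = (unit * (span_len // spec.step + 1))[:span_len]
            background[lo - 1 : hi] = stretch
            for k in range(spec.tandem):
                truths.append(PlantTruth(m.id, spec.position + k * spec.step, mb, 100.0))
        else:
            background[lo - 1 : hi] = window
            truths.append(PlantTruth(m.id, spec.position, expected, 100.0 * expected / mb))

    transcript = Transcript(
        id=f"synthetic_tx_seed{seed}",
        sequence="".join(background),
        gene=f"SYNTX{seed}",
        utr5_len=config.utr5_len,
        cds_len=config.cds_len,
        utr3_len=config.utr3_len,
    )
    return SynthBundle(
        mirnas=tuple(mirnas),
        transcript=transcript,
        truth=SynthTruth(tuple(truths)),
        seed=seed,
    )


@dataclass(frozen=True)
class RecoveryReport:
    n_expected: int  # plants whose a-priori ratio clears the threshold
    n_recovered: int  # of those, found at the exact position
    n_expected_miss: int  # plants below threshold, correctly absent
    n_extra: int  # reported sites not planted (background or shifted hits)
    completeness: float
    sound: bool  # every reported bond total equals a recount


def recovery_report(
    truth: SynthTruth,
    scan_output,
    threshold_pct: float = 87.0,
) -> RecoveryReport:
    """Compare scanner output with planted ground truth.

    ``scan_output`` is a list of DuplexAlignment from :func:`~mircluster.duplex.scan`
    over the bundle's miRNAs.  Soundness recounts every reported
    alignment position by position.
    """
    from .duplex import bond_count  # per-pair recount

    reported = {(a.mirna_id, a.start): a for a in scan_output}
    expected = [p for p in truth.plants if p.expected_ratio_pct >= threshold_pct]
    missed_ok = [p for p in truth.plants if p.expected_ratio_pct < threshold_pct]
    recovered = 0
    for p in expected:
        a = reported.get((p.mirna_id, p.start))
        if a is not None and a.bonds_total == p.expected_bonds:
            recovered += 1
    planted_keys = {(p.mirna_id, p.start) for p in truth.plants}
    extra = sum(1 for k in reported if k not in planted_keys)
    sound = all(
        a.bonds_total
        == sum(
            bond_count(a.mirna_seq[::-1][i], a.window_seq[i])
            for i in range(a.length)
        )
        for a in scan_output
    )
    return RecoveryReport(
        n_expected=len(expected),
        n_recovered=recovered,
        n_expected_miss=len(missed_ok),
        n_extra=extra,
        completeness=(recovered / len(expected)) if expected else 1.0,
        sound=sound,
    )
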