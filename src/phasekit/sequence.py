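"""Charge, composition and patterning metrics for disordered protein sequences.

Intrinsically disordered, low-complexity proteins — such as the glycine-rich
proteins (GRPs) of tick saliva — are characterised less by their fold than by
bulk sequence statistics: the fraction of charged residues (FCR), the net
charge per residue (NCPR) and its distribution along the chain, the balance of
polar versus non-polar content, and the spacing of aromatic "sticker"
residues. This module computes those metrics:

* :func:`composition` — per-residue counts and category fractions under a
  configurable residue grouping (glycine always reported on its own).
* :func:`net_charge` — formal or Henderson–Hasselbalch (pH-dependent) net
  charge in elementary-charge units, with optional terminal groups.
* :func:`ncpr_profile` — windowed NCPR along the sequence plus the global
  (f+, f−) statistics and the Das–Pappu conformational-class region.
* :func:`aromatic_spacing` — gaps between consecutive aromatic residues,
  the "periodic sticker" statistic of low-complexity adhesives.

Sequences are held in :class:`ResidueSequence`, a validated one-letter-code
container; FASTA input goes through Biopython.
"""

from __future__ import annotations

import io
import urllib.request
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .exceptions import ConfigurationError, FormatError, ValidationError

__all__ = [
    "CANONICAL_RESIDUES",
    "ResidueSequence",
    "ChargeModel",
    "CompositionReport",
    "ChargeProfile",
    "AromaticSpacing",
    "DEFAULT_PKA",
    "DEFAULT_CATEGORY_MAP",
    "read_fasta",
    "fetch_uniprot",
    "composition",
    "net_charge",
    "ncpr_profile",
    "aromatic_spacing",
]

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default side-chain / terminal pKa values. Published tables differ by a few
#: tenths of a unit; the table is user-overridable because net charges at
#: physiological pH are sensitive to it at the ±0.3 e level.
DEFAULT_PKA: Mapping[str, float] = {
    "nterm": 9.0,
    "cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 6.0,
    "K": 10.0,
    "R": 12.0,
}

#: Default composition categories. Glycine is singled out because it is the
#: defining residue of GRPs; the remaining grouping (notably E, R, K under
#: "polar") follows the convention used for GRP composition reporting and is
#: configurable — it is a convention, not a law.
DEFAULT_CATEGORY_MAP: Mapping[str, frozenset] = {
    "glycine": frozenset("G"),
    "other_nonpolar": frozenset("APMC"),
    "polar": frozenset("STNQDEKRH"),
    "hydrophobic": frozenset("VIL"),
    "aromatic": frozenset("FYW"),
}

_FORMAL_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}
_BASIC_SIDECHAINS = ("K", "R", "H")
_ACIDIC_SIDECHAINS = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class ResidueSequence:
    """A named amino-acid sequence restricted to the 20 canonical residues.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header or user label).
    residues : str
        One-letter codes; lowercase input is normalised to uppercase.
    region_label : str, optional
        Free-text annotation such as ``"signal 1-19"`` or ``"mature 20-96"``.
    """

    id: str
    residues: str
    region_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        for i, aa in enumerate(self.residues):
            if aa not in CANONICAL_RESIDUES:
                raise ValidationError(
                    f"sequence {self.id!r}: non-canonical residue {aa!r} "
                    f"at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def fragment(self, start: int, end: int, label: str | None = None) -> "ResidueSequence":
        """Extract residues ``start``..``end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self)):
            raise ValidationError(
                f"fragment {start}-{end} outside 1-{len(self)} for {self.id!r}"
            )
        return ResidueSequence(
            id=f"{self.id}[{start}-{end}]",
            residues=self.residues[start - 1 : end],
            region_label=label,
        )


@dataclass(frozen=True)
class ChargeModel:
    """How residue charges are assigned.

    ``mode="formal"`` gives integer charges (+1 K/R, −1 D/E, 0 otherwise —
    histidine carries no formal charge). ``mode="henderson_hasselbalch"``
    gives fractional protonation-state charges at a given pH from the pKa
    table, optionally including the free N- and C-termini.
    """

    mode: str = "henderson_hasselbalch"
    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    include_termini: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("formal", "henderson_hasselbalch"):
            raise ConfigurationError(f"unknown charge mode {self.mode!r}")
        missing = set(DEFAULT_PKA) - set(self.pka)
        if missing:
            raise ConfigurationError(f"pKa table missing entries: {sorted(missing)}")
        for key, val in self.pka.items():
            if not (0.0 < float(val) < 14.0):
                raise ConfigurationError(f"pKa[{key!r}]={val} outside (0, 14)")


@dataclass(frozen=True)
class CompositionReport:
    """Residue counts and category fractions for one sequence."""

    sequence_id: str
    length: int
    residue_counts: Mapping[str, int]
    category_counts: Mapping[str, int]
    category_fractions: Mapping[str, float]

    def as_rows(self) -> list[dict]:
        """Tidy rows (one per category) for tabular output."""
        return [
            {
                "sequence_id": self.sequence_id,
                "category": cat,
                "count": self.category_counts[cat],
                "fraction": self.category_fractions[cat],
            }
            for cat in self.category_counts
        ]


@dataclass(frozen=True)
class ChargeProfile:
    """Windowed NCPR profile plus global charge-patterning statistics."""

    sequence_id: str
    window: int
    positions: np.ndarray  # 1-based residue positions
    ncpr: np.ndarray  # windowed net charge per residue
    global_ncpr: float
    global_fcr: float
    fraction_positive: float
    fraction_negative: float
    das_pappu_region: str


@dataclass(frozen=True)
class AromaticSpacing:
    """Gaps (in residues) between consecutive aromatic positions."""

    sequence_id: str
    aromatic_positions: tuple  # 1-based
    gaps: tuple
    n_aromatic: int
    median_gap: float | None
    min_gap: int | None
    max_gap: int | None


def read_fasta(path: str | Path) -> list[ResidueSequence]:
    """Read a protein FASTA file into validated :class:`ResidueSequence` records.

    Raises
    ------
    FormatError
        If the file contains no records.
    ValidationError
        If any record contains a non-canonical letter (the position is named).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return [ResidueSequence(id=rec.id, residues=str(rec.seq)) for rec in records]


def fetch_uniprot(accession: str, timeout: float = 30.0) -> ResidueSequence:
    """Download one UniProtKB record as FASTA and return its sequence.

    Requires network access; intended for interactive use (e.g. pulling the
    tick GRP record Q4PME3 to reproduce published charge values).
    """
    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError(f"UniProt returned no FASTA record for {accession}")
    return ResidueSequence(id=accession, residues=str(records[0].seq))


def composition(
    seq: ResidueSequence,
    category_map: Mapping[str, Iterable[str]] | None = None,
) -> CompositionReport:
    """Per-residue counts and category fractions.

    The category map must cover all 20 canonical residues exactly once.
    Fractions sum to 1 (up to rounding); counts sum to the sequence length.
    """
    cmap = {k: frozenset(v) for k, v in (category_map or DEFAULT_CATEGORY_MAP).items()}
    covered = frozenset().union(*cmap.values()) if cmap else frozenset()
    missing = CANONICAL_RESIDUES - covered
    if missing:
        raise ConfigurationError(
            f"category map does not cover residues: {''.join(sorted(missing))}"
        )
    overlaps = [
        (a, b)
        for a in cmap
        for b in cmap
        if a < b and cmap[a] & cmap[b]
    ]
    if overlaps:
        raise ConfigurationError(f"category map has overlapping categories: {overlaps}")

    counts = Counter(seq.residues)
    n = len(seq)
    cat_counts = {
        cat: sum(counts.get(aa, 0) for aa in members) for cat, members in cmap.items()
    }
    cat_fracs = {cat: c / n for cat, c in cat_counts.items()}
    return CompositionReport(
        sequence_id=seq.id,
        length=n,
        residue_counts=dict(counts),
        category_counts=cat_counts,
        category_fractions=cat_fracs,
    )


def _hh_positive(pH: float, pka: float) -> float:
    """Average charge of a basic (protonatable) site at this pH."""
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def _hh_negative(pH: float, pka: float) -> float:
    """Average charge magnitude of an acidic (deprotonatable) site at this pH."""
    return 1.0 / (1.0 + 10.0 ** (pka - pH))


def net_charge(
    seq: ResidueSequence,
    pH: float = 7.4,
    model: ChargeModel | None = None,
) -> float:
    """Net charge of the sequence in elementary-charge units.

    Formal mode counts +1 per K/R and −1 per D/E (an integer). The
    Henderson–Hasselbalch mode sums average protonation-state charges: for a
    basic site ``+1/(1+10^(pH−pKa))``, for an acidic site ``−1/(1+10^(pKa−pH))``,
    over H/K/R (+ free N-terminus) and D/E/C/Y (+ free C-terminus).
    """
    if not (0.0 <= pH <= 14.0):
        raise ValidationError(f"pH {pH} outside [0, 14]")
    model = model or ChargeModel()
    if model.mode == "formal":
        return float(sum(_FORMAL_CHARGE.get(aa, 0) for aa in seq))

    counts = Counter(seq.residues)
    q = 0.0
    for aa in _BASIC_SIDECHAINS:
        q += counts.get(aa, 0) * _hh_positive(pH, model.pka[aa])
    for aa in _ACIDIC_SIDECHAINS:
        q -= counts.get(aa, 0) * _hh_negative(pH, model.pka[aa])
    if model.include_termini:
        q += _hh_positive(pH, model.pka["nterm"])
        q -= _hh_negative(pH, model.pka["cterm"])
    return q


def _das_pappu_region(f_plus: float, f_minus: float) -> str:
    """Classify a sequence on the (f+, f−) diagram of disordered-chain classes.

    R1: weak polyampholytes/polyelectrolytes (globule formers); R2: boundary
    ("Janus") region; R3: strong polyampholytes (coils/hairpins); R4/R5:
    strong negative/positive polyelectrolytes.
    """
    fcr = f_plus + f_minus
    if f_plus > 0.35:
        return "R5"
    if f_minus > 0.35:
        return "R4"
    if fcr > 0.35:
        return "R3"
    if fcr < 0.25:
        return "R1"
    return "R2"


def ncpr_profile(
    seq: ResidueSequence,
    window: int = 5,
    model: ChargeModel | None = None,
) -> ChargeProfile:
    """Windowed net charge per residue along the chain, plus global statistics.

    Per-position values are the mean formal charge over a centred window
    (truncated at the sequence edges, not padded). Global f+ and f− are the
    fractions of formally positive (K, R) and negative (D, E) residues;
    FCR = f+ + f−, NCPR = f+ − f−. The (f+, f−) pair places the sequence in
    a Das–Pappu diagram region R1–R5.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"window must be an odd integer >= 1, got {window}")
    if window > len(seq):
        raise ConfigurationError(
            f"window {window} exceeds sequence length {len(seq)}"
        )
    charges = np.array([_FORMAL_CHARGE.get(aa, 0) for aa in seq], dtype=float)
    half = window // 2
    n = len(seq)
    ncpr = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        ncpr[i] = charges[lo:hi].mean()

    f_plus = sum(1 for aa in seq if _FORMAL_CHARGE.get(aa, 0) > 0) / n
    f_minus = sum(1 for aa in seq if _FORMAL_CHARGE.get(aa, 0) < 0) / n
    return ChargeProfile(
        sequence_id=seq.id,
        window=window,
        positions=np.arange(1, n + 1),
        ncpr=ncpr,
        global_ncpr=f_plus - f_minus,
        global_fcr=f_plus + f_minus,
        fraction_positive=f_plus,
        fraction_negative=f_minus,
        das_pappu_region=_das_pappu_region(f_plus, f_minus),
    )


def aromatic_spacing(
    seq: ResidueSequence,
    aromatic_set: Iterable[str] = ("F", "Y", "W"),
) -> AromaticSpacing:
    """Gaps between consecutive aromatic residues.

    A gap is the difference between successive aromatic positions, so
    ``FGGGF`` has one gap of 4. Fewer than two aromatics gives an empty gap
    list. Periodic, well-spaced aromatics (gaps of ~3–10) are the hallmark
    "sticker" pattern of phase-separating low-complexity sequences.
    """
    aset = frozenset(a.upper() for a in aromatic_set)
    positions = tuple(i + 1 for i, aa in enumerate(seq) if aa in aset)
    gaps = tuple(b - a for a, b in zip(positions, positions[1:]))
    return AromaticSpacing(
        sequence_id=seq.id,
        aromatic_positions=positions,
        gaps=gaps,
        n_aromatic=len(positions),
        median_gap=float(np.median(gaps)) if gaps else None,
        min_gap=min(gaps) if gaps else None,
        max_gap=max(gaps) if gaps else None,
    )
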