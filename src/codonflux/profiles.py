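"""Coding sequences and translational speed profiles.

A speed profile assigns each codon of a CDS its expected translation
time under one tRNA pool, then averages the times over a centered
sliding window (default 19 codons, the ribosomal footprint) to capture
local elongation speed.  Window edges are truncated: near the termini
the effective window shrinks so the smoothed profile keeps the length of
the codon list, which keeps length normalization comparable across
genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .codon_rates import RateTable, STOP_CODONS

__all__ = [
    "START_CODONS",
    "CodingSequence",
    "SpeedProfile",
    "CdsError",
    "AmbiguousBaseError",
    "ProfileUnusableError",
    "read_fasta",
    "read_genbank",
    "raw_profile",
    "smooth",
    "profile",
    "profiles_for_conditions",
    "write_profile_tsv",
]

# Bacterial initiation codons.
START_CODONS = frozenset({"AUG", "GUG", "UUG"})
_VALID_BASES = frozenset("ACGU")


class CdsError(ValueError):
    """A coding sequence violates the model's structural assumptions."""


class AmbiguousBaseError(CdsError):
    """Sequence contains non-ACGT/U characters; gene should be skipped."""


class ProfileUnusableError(ValueError):
    """A codon without a finite expected time poisons the profile."""


@dataclass(frozen=True)
class CodingSequence:
    """A CDS plus its derived codon list (RNA alphabet, 5'->3').

    ``category`` tags special sequence classes: ``"essential"``,
    ``"untranslated"`` (profiled in annotation frame without codon
    validation, in-frame stops dropped), or ``None``.  A trailing stop
    codon is stripped from the translated codon list; profiles model
    elongation only.
    """

    id: str
    nucleotides: str
    category: Optional[str] = None
    genome_start: Optional[int] = None  # 1-based
    strand: Optional[int] = None
    strict: bool = True
    codons: Tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        seq = self.nucleotides.strip().upper().replace("T", "U")
        object.__setattr__(self, "nucleotides", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise AmbiguousBaseError(
                f"{self.id}: ambiguous or invalid base(s) {sorted(bad)}"
            )
        untranslated = self.category == "untranslated"
        if len(seq) % 3 != 0:
            if self.strict and not untranslated:
                raise CdsError(f"{self.id}: length {len(seq)} not divisible by 3")
            seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if not untranslated:
            if codons and codons[-1] in STOP_CODONS:
                codons = codons[:-1]
            if not codons:
                raise CdsError(f"{self.id}: no translated codons")
            internal_stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
            if internal_stops:
                msg = f"{self.id}: internal stop codon at codon position {internal_stops[0] + 1}"
                if self.strict:
                    raise CdsError(msg)
                warnings.warn(msg, stacklevel=2)
            if self.strict and codons[0] not in START_CODONS:
                raise CdsError(f"{self.id}: first codon {codons[0]} is not a start codon")
        else:
            # Profile untranslated sequences as if coding, frame from the
            # annotation start; stops carry no rate in this model and are
            # dropped rather than poisoning the profile.
            codons = [c for c in codons if c not in STOP_CODONS]
            if not codons:
                raise CdsError(f"{self.id}: untranslated sequence has no non-stop codons")
        object.__setattr__(self, "codons", tuple(codons))

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def gc_fraction(self) -> float:
        seq = self.nucleotides
        return (seq.count("G") + seq.count("C")) / len(seq) if seq else math.nan


@dataclass(frozen=True)
class SpeedProfile:
    """Raw and smoothed per-codon time series of one gene under one condition."""

    gene_id: str
    condition: str
    raw_times: np.ndarray
    smoothed_times: np.ndarray
    window: int = 19

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_times, dtype=float)
        smo = np.asarray(self.smoothed_times, dtype=float)
        object.__setattr__(self, "raw_times", raw)
        object.__setattr__(self, "smoothed_times", smo)
        if raw.shape != smo.shape:
            raise ValueError(f"{self.gene_id}: raw/smoothed length mismatch")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 1, got {self.window}")

    @property
    def speed(self) -> np.ndarray:
        """Reciprocal of the smoothed times, elementwise."""
        return 1.0 / self.smoothed_times

    def __len__(self) -> int:
        return len(self.raw_times)


# ---------------------------------------------------------------------------
# Sequence input
# ---------------------------------------------------------------------------

def read_fasta(path, strict: bool = True, category: Optional[str] = None) -> List[CodingSequence]:
    """Read a multi-FASTA of CDS; genes with ambiguous bases are skipped with a warning."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(
                CodingSequence(
                    id=rec.id, nucleotides=str(rec.seq), category=category, strict=strict
                )
            )
        except AmbiguousBaseError as exc:
            warnings.warn(f"skipping {rec.id}: {exc}", stacklevel=2)
    return out


def read_genbank(path, strict: bool = False) -> List[CodingSequence]:
    """Extract CDS features from a GenBank flat file, strand-aware.

    Minus-strand features are reverse-complemented before the codon
    split.  ``genome_start`` is the 1-based leftmost genomic coordinate
    of the feature; pseudo genes are tagged ``category="pseudo"``.
    """
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
            seq = str(feat.extract(rec.seq))
            category = "pseudo" if "pseudo" in feat.qualifiers else None
            try:
                out.append(
                    CodingSequence(
                        id=name,
                        nucleotides=seq,
                        category=category,
                        genome_start=int(feat.location.start) + 1,
                        strand=feat.location.strand,
                        strict=strict,
                    )
                )
            except AmbiguousBaseError as exc:
                warnings.warn(f"skipping {name}: {exc}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def raw_profile(cds: CodingSequence, rates: RateTable) -> np.ndarray:
    """Expected time per codon, in sequence order."""
    if len(cds.codons) == 0:
        raise CdsError(f"{cds.id}: empty codon list")
    try:
        times = np.array([rates.t[c] for c in cds.codons], dtype=float)
    except KeyError as exc:
        raise ProfileUnusableError(f"{cds.id}: codon {exc} absent from rate table") from exc
    if np.isinf(times).any():
        bad = sorted({c for c in cds.codons if math.isinf(rates.t[c])})
        raise ProfileUnusableError(
            f"{cds.id}: codon(s) {bad} have no recognizing tRNA at positive "
            f"availability under condition {rates.condition!r}"
        )
    return times


def smooth(times: Sequence[float], window: int = 19) -> np.ndarray:
    """Centered sliding-window mean with truncation at the termini.

    Position *j* receives the arithmetic mean of the values within
    ``window // 2`` codons of *j*; near the ends the window shrinks to
    what the sequence provides, so output length equals input length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("times must be a nonempty 1-D sequence")
    if window == 1:
        return arr.copy()
    return (
        pd.Series(arr)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def profile(cds: CodingSequence, rates: RateTable, window: int = 19) -> SpeedProfile:
    """Raw lookup + smoothing, packaged as a :class:`SpeedProfile`."""
    raw = raw_profile(cds, rates)
    return SpeedProfile(
        gene_id=cds.id,
        condition=rates.condition,
        raw_times=raw,
        smoothed_times=smooth(raw, window),
        window=window,
    )


def profiles_for_conditions(
    genes: Iterable[CodingSequence],
    rate_tables: Iterable[RateTable],
    window: int = 19,
) -> dict:
    """All (condition, gene) profiles; unusable genes are dropped with a warning.

    Returns ``{condition: {gene_id: SpeedProfile}}``.  A gene containing
    a codon that nothing decodes under some condition is excluded from
    that condition only.
    """
    genes = list(genes)
    out: dict = {}
    for rt in rate_tables:
        per_gene = {}
        for cds in genes:
            try:
                per_gene[cds.id] = profile(cds, rt, window)
            except ProfileUnusableError as exc:
                warnings.warn(str(exc), stacklevel=2)
        out[rt.condition] = per_gene
    return out


def write_profile_tsv(profiles: Iterable[SpeedProfile], path, genes=None) -> None:
    """Per-position table: gene, position (1-based), codon, raw/smoothed time, speed."""
    codon_lookup = {g.id: g.codons for g in genes} if genes is not None else {}
    frames = []
    for p in profiles:
        codons = codon_lookup.get(p.gene_id)
        frames.append(
            pd.DataFrame(
                {
                    "gene": p.gene_id,
                    "position": np.arange(1, len(p) + 1),
                    "codon": list(codons) if codons is not None else "",
                    "raw_time": p.raw_times,
                    "smoothed_time": p.smoothed_times,
                    "speed": p.speed,
                    "condition": p.condition,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
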