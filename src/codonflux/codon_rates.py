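"""Per-codon adaptiveness, translation rates and expected times.

The adaptiveness of codon *i* is the availability-weighted sum over the
tRNA isoacceptors recognizing it,

    W_i = sum_j (1 - s_ij) * conc_j ,

where ``s_ij`` is the selective constraint of the particular
codon-anticodon wobble pairing (0 for a Watson-Crick coupling).
Recognition follows Crick's wobble rules per codon box of four
third-position variants, with two bacterial exceptions: AUA is read only
by the lysidine-modified Ile species, and AUG only by elongator Met.

Rates normalize W over all codon types and rescale by the total pool so
that pools of different overall size remain comparable:

    r_i = W_i / sum_j W_j * sum_k conc_k ,     t_i = 1 / r_i .

The expected time ``t_i`` (exponential-waiting-time view of tRNA
selection) is the per-codon unit from which speed profiles are built.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, NamedTuple, Optional, Sequence, Tuple

import yaml

from .trna_io import TRNAPool, TRNASpecies, bundled_path

__all__ = [
    "PAIRING_KINDS",
    "DEFAULT_S_VALUES",
    "DEFAULT_OVERRIDES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "WobbleRules",
    "Recognizer",
    "RecognitionMap",
    "AdaptivenessTable",
    "RateTable",
    "build_recognition_map",
    "adaptiveness",
    "rates",
    "rate_table",
    "fold_changes",
    "write_rate_table",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
SENSE_CODONS: Tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGU", repeat=3)) if c not in STOP_CODONS
)

PAIRING_KINDS = (
    "A34:U3", "G34:C3", "U34:A3", "C34:G3",       # Watson-Crick (I34:U3 folded into A34:U3)
    "G34:U3", "I34:C3", "I34:A3", "U34:G3",       # wobble
    "L34:A3",                                     # lysidine-C34 reading AUA
)

# Selective constraints of the tAI literature; Watson-Crick pairings cost
# nothing, wobble pairings are penalized, the near-forbidden I34:A3 makes
# inosine reading of codon-3' A marginal.
DEFAULT_S_VALUES: Dict[str, float] = {
    "A34:U3": 0.0,
    "G34:C3": 0.0,
    "U34:A3": 0.0,
    "C34:G3": 0.0,
    "G34:U3": 0.41,
    "I34:C3": 0.28,
    "I34:A3": 0.9999,
    "U34:G3": 0.68,
    "L34:A3": 0.89,
}

# CGA read by the ACG anticodon: with the generic I34:A3 value the CGA
# rate is ~2 orders of magnitude below the next-slowest codon and
# dominates every analysis; the standard remedy is this empirically
# better-matching constraint.
DEFAULT_OVERRIDES: Dict[Tuple[str, str], float] = {("CGA", "ACG"): 0.9172}


@dataclass(frozen=True)
class WobbleRules:
    """Pairing-kind constraints plus per-(codon, anticodon) overrides."""

    s: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_S_VALUES))
    overrides: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_OVERRIDES)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", dict(self.s))
        object.__setattr__(self, "overrides", dict(self.overrides))
        unknown = set(self.s) - set(PAIRING_KINDS)
        if unknown:
            raise ValueError(f"unknown pairing kinds: {sorted(unknown)}")
        for kind in PAIRING_KINDS:
            if kind not in self.s:
                raise ValueError(f"missing s-value for pairing kind {kind}")
        for kind, v in self.s.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"s[{kind}] = {v} outside [0, 1]")
        for (codon, ac), v in self.overrides.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"override s for ({codon}, {ac}) = {v} outside [0, 1]")

    @classmethod
    def default(cls) -> "WobbleRules":
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "WobbleRules":
        """Load rules from a key/value config file.

        Layout::

            s_values:
              G34:U3: 0.41
              ...
            overrides:
              CGA:ACG: 0.9172

        Keys absent from the file keep their defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        s = dict(DEFAULT_S_VALUES)
        s.update(raw.get("s_values", {}))
        overrides = dict(DEFAULT_OVERRIDES)
        for key, v in raw.get("overrides", {}).items():
            codon, ac = key.split(":")
            overrides[(codon.upper().replace("T", "U"), ac.upper().replace("T", "U"))] = v
        return cls(s=s, overrides=overrides)

    def effective_s(self, codon: str, anticodon: str, kind: str) -> float:
        return self.overrides.get((codon, anticodon), self.s[kind])

    @classmethod
    def bundled(cls) -> "WobbleRules":
        return cls.from_yaml(bundled_path("s_values.yaml"))


class Recognizer(NamedTuple):
    species: str
    anticodon: str
    kind: str


@dataclass(frozen=True)
class RecognitionMap:
    """codon -> recognizing (species, anticodon, pairing-kind) entries."""

    entries: Mapping[str, Tuple[Recognizer, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    def __getitem__(self, codon: str) -> Tuple[Recognizer, ...]:
        return self.entries[codon]

    @property
    def species_names(self) -> frozenset:
        return frozenset(r.species for recs in self.entries.values() for r in recs)


def build_recognition_map(species: Iterable[TRNASpecies]) -> RecognitionMap:
    """Enumerate codon-anticodon recognition under Crick wobble rules.

    For each anticodon the two codon prefix bases are the reverse
    complement of anticodon positions 35-36; the wobble base (34)
    determines which third-position codon bases are read:

    ======  =====================================
    wobble  codon third base (pairing kind)
    ======  =====================================
    A       U (A34:U3); +C (I34:C3), +A (I34:A3) when inosine-modified
    G       C (G34:C3), U (G34:U3)
    U       A (U34:A3), G (U34:G3)
    C       G (C34:G3)
    ======  =====================================

    Exceptions: a lysidine-modified species reads only codon-3' A
    (L34:A3, the AUA-reading Ile2); the AUA codon keeps only lysidine
    readers; AUG keeps only elongator Met via C34:G3.  Stop codons are
    excluded.  Codons with no recognizer get empty entries.
    """
    species = list(species)
    entries: Dict[str, list] = {c: [] for c in SENSE_CODONS}
    aa = {}
    for sp in species:
        aa[sp.name] = sp.amino_acid
        ac = sp.anticodon
        prefix = _COMPLEMENT[ac[2]] + _COMPLEMENT[ac[1]]
        if sp.modification == "lysidine":
            targets = [(prefix + "A", "L34:A3")]
        elif ac[0] == "A":
            targets = [(prefix + "U", "A34:U3")]
            if sp.inosine34:
                targets += [(prefix + "C", "I34:C3"), (prefix + "A", "I34:A3")]
        elif ac[0] == "G":
            targets = [(prefix + "C", "G34:C3"), (prefix + "U", "G34:U3")]
        elif ac[0] == "U":
            targets = [(prefix + "A", "U34:A3"), (prefix + "G", "U34:G3")]
        else:  # C34
            targets = [(prefix + "G", "C34:G3")]
        for codon, kind in targets:
            if codon in STOP_CODONS:
                continue
            entries[codon].append(Recognizer(sp.name, ac, kind))
    entries["AUA"] = [r for r in entries["AUA"] if r.kind == "L34:A3"]
    entries["AUG"] = [
        r for r in entries["AUG"] if aa.get(r.species) == "M" and r.kind == "C34:G3"
    ]
    return RecognitionMap({c: tuple(v) for c, v in entries.items()})


@dataclass(frozen=True)
class AdaptivenessTable:
    """W_i per codon for one condition; W = 0 where nothing decodes."""

    W: Mapping[str, float]
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "W", dict(self.W))
        for codon, w in self.W.items():
            if w < 0:
                raise ValueError(f"W[{codon}] = {w} is negative")

    @property
    def total(self) -> float:
        return float(sum(self.W.values()))


@dataclass(frozen=True)
class RateTable:
    """Normalized rates r and expected times t = 1/r for one condition.

    Codons whose adaptiveness is zero under the pool have no defined
    rate; they are listed in ``undefined_codons`` and carry ``t = inf``.
    The sum of the defined rates equals ``total_pool`` by construction.
    """

    r: Mapping[str, float]
    t: Mapping[str, float]
    total_pool: float
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", dict(self.r))
        object.__setattr__(self, "t", dict(self.t))

    @property
    def undefined_codons(self) -> frozenset:
        return frozenset(c for c, t in self.t.items() if math.isinf(t))

    @property
    def codons(self) -> frozenset:
        return frozenset(self.t)


def adaptiveness(
    pool: TRNAPool,
    recognition: RecognitionMap,
    rules: Optional[WobbleRules] = None,
) -> AdaptivenessTable:
    """W_i = sum over recognizing species of (1 - s) * concentration."""
    rules = rules if rules is not None else WobbleRules.default()
    missing = recognition.species_names - pool.species_names
    if missing:
        raise ValueError(f"species in recognition map missing from pool: {sorted(missing)}")
    W = {}
    for codon, recs in recognition.entries.items():
        W[codon] = sum(
            (1.0 - rules.effective_s(codon, rec.anticodon, rec.kind))
            * pool.concentration[rec.species]
            for rec in recs
        )
    return AdaptivenessTable(W=W, condition=pool.condition)


def rates(W: AdaptivenessTable, pool: TRNAPool) -> RateTable:
    """Normalize adaptiveness into rates and expected times (see module docs)."""
    sw = W.total
    if sw <= 0:
        raise ValueError("all adaptiveness values are zero; no rates can be defined")
    total = pool.total
    r: Dict[str, float] = {}
    t: Dict[str, float] = {}
    for codon, w in W.W.items():
        if w > 0:
            ri = w / sw * total
            r[codon] = ri
            t[codon] = 1.0 / ri
        else:
            t[codon] = math.inf
    return RateTable(r=r, t=t, total_pool=total, condition=W.condition)


def rate_table(
    pool: TRNAPool,
    species: Iterable[TRNASpecies],
    rules: Optional[WobbleRules] = None,
    recognition: Optional[RecognitionMap] = None,
) -> RateTable:
    """Convenience pipeline: recognition map -> adaptiveness -> rates."""
    recognition = recognition if recognition is not None else build_recognition_map(species)
    return rates(adaptiveness(pool, recognition, rules), pool)


def fold_changes(rates_a: RateTable, rates_b: RateTable) -> Dict[str, float]:
    """Per-codon rate ratio r_b / r_a between two conditions.

    Codons without a defined rate in either table are excluded.
    Identical tables give 1.0 everywhere; a uniformly scaled pool gives
    the scale factor everywhere.
    """
    if rates_a.codons != rates_b.codons:
        raise ValueError("rate tables cover different codon sets")
    return {
        c: rates_b.r[c] / rates_a.r[c]
        for c in rates_a.r
        if c in rates_b.r
    }


def write_rate_table(rt: RateTable, path, W: Optional[AdaptivenessTable] = None) -> None:
    """Export as TSV with columns codon, W, r, t, condition."""
    import pandas as pd

    rows = []
    for codon in sorted(rt.t):
        rows.append(
            {
                "codon": codon,
                "W": W.W[codon] if W is not None else float("nan"),
                "r": rt.r.get(codon, float("nan")),
                "t": rt.t[codon],
                "condition": rt.condition,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
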