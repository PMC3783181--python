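"""tRNA availability data model and readers.

A *pool* is the set of tRNA isoacceptor availabilities measured under one
condition (one growth rate, or one time point after an amino-acid
starvation).  A :class:`ConditionSet` bundles the pools of one experiment
together with the label of its reference condition.

Concentration units are opaque: whatever the source table reports is
carried through unchanged, and every downstream quantity (rate, expected
time, threshold) lives in the units induced by the input table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TRNASpecies",
    "TRNAPool",
    "ConditionSet",
    "read_anticodon_map",
    "read_pool_table",
    "write_pool_table",
    "split_grouped_isoacceptors",
    "effective_availability",
    "ecoli_anticodon_map",
    "bundled_path",
]

_RNA_BASES = frozenset("ACGU")
_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _to_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class TRNASpecies:
    """One tRNA isoacceptor.

    Parameters
    ----------
    name:
        Isoacceptor label, e.g. ``"Leu1"``.
    amino_acid:
        One-letter amino-acid code.
    anticodon:
        3-mer over {A,C,G,U}, written 5'->3'; position 34 (the wobble
        base) is the first character.
    modification:
        ``"lysidine"`` marks the bacterial Ile2-type species whose
        modified C34 reads AUA instead of AUG; ``"none"`` otherwise.
    inosine34:
        Whether an A at position 34 is deaminated to inosine (the
        bacterial default), extending its reading from codon-3' U to
        U, C and (weakly) A.
    """

    name: str
    amino_acid: str
    anticodon: str
    modification: str = "none"
    inosine34: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "anticodon", _to_rna(self.anticodon))
        if len(self.anticodon) != 3 or not set(self.anticodon) <= _RNA_BASES:
            raise ValueError(
                f"{self.name}: anticodon must be a 3-mer over A/C/G/U, got {self.anticodon!r}"
            )
        if self.amino_acid not in _AMINO_ACIDS:
            raise ValueError(f"{self.name}: unknown amino acid {self.amino_acid!r}")
        if self.modification not in ("none", "lysidine"):
            raise ValueError(f"{self.name}: unknown modification {self.modification!r}")

    @property
    def wobble_base(self) -> str:
        """First anticodon base (position 34)."""
        return self.anticodon[0]


@dataclass(frozen=True)
class TRNAPool:
    """Isoacceptor availabilities under one condition.

    ``concentration`` maps isoacceptor name to a nonnegative quantity in
    the (opaque) units of the source table.  ``charged_fraction``, when
    present, maps isoacceptor name to the aminoacylated proportion in
    [0, 1].
    """

    condition: str
    concentration: Mapping[str, float]
    charged_fraction: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentration", dict(self.concentration))
        for name, c in self.concentration.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}: {c}")
        if self.charged_fraction is not None:
            object.__setattr__(self, "charged_fraction", dict(self.charged_fraction))
            for name, f in self.charged_fraction.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"charged fraction for {name!r} outside [0, 1]: {f}")

    @property
    def species_names(self) -> frozenset:
        return frozenset(self.concentration)

    @property
    def total(self) -> float:
        return float(sum(self.concentration.values()))

    def scaled(self, factor: float, condition: Optional[str] = None) -> "TRNAPool":
        """Uniformly scale every concentration by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError(f"scale factor must be nonnegative, got {factor}")
        return TRNAPool(
            condition=condition if condition is not None else self.condition,
            concentration={k: v * factor for k, v in self.concentration.items()},
            charged_fraction=self.charged_fraction,
        )


@dataclass(frozen=True)
class ConditionSet:
    """Ordered pools of one experiment plus its reference condition."""

    reference_condition: str
    pools: Sequence[TRNAPool]
    species: Mapping[str, TRNASpecies] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        object.__setattr__(self, "species", dict(self.species))
        if not self.pools:
            raise ValueError("ConditionSet needs at least one pool")
        names = {p.condition for p in self.pools}
        if self.reference_condition not in names:
            raise ValueError(
                f"reference condition {self.reference_condition!r} not among {sorted(names)}"
            )
        ref_set = self.pools[0].species_names
        for p in self.pools[1:]:
            if p.species_names != ref_set:
                raise ValueError(
                    f"pool {p.condition!r} has a different species set than "
                    f"{self.pools[0].condition!r}"
                )

    @property
    def conditions(self) -> tuple:
        return tuple(p.condition for p in self.pools)

    def pool(self, condition: str) -> TRNAPool:
        for p in self.pools:
            if p.condition == condition:
                return p
        raise KeyError(condition)

    @property
    def reference(self) -> TRNAPool:
        return self.pool(self.reference_condition)

    @property
    def species_list(self) -> tuple:
        return tuple(self.species.values())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_anticodon_map(path) -> dict:
    """Read an isoacceptor->anticodon table.

    TSV with columns ``name``, ``amino_acid``, ``anticodon`` and an
    optional ``modification`` column (``lysidine`` or ``none``).
    Returns a dict mapping name to :class:`TRNASpecies`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"name", "amino_acid", "anticodon"}
    if not required <= set(df.columns):
        raise ValueError(f"anticodon map must have columns {sorted(required)}")
    out: dict = {}
    for row in df.itertuples(index=False):
        mod = getattr(row, "modification", "none")
        if pd.isna(mod):
            mod = "none"
        out[row.name] = TRNASpecies(
            name=row.name,
            amino_acid=row.amino_acid,
            anticodon=row.anticodon,
            modification=mod,
        )
    return out


def read_pool_table(
    table,
    anticodon_map,
    charging=None,
    reference_condition: Optional[str] = None,
) -> ConditionSet:
    """Read a multi-condition availability table into a :class:`ConditionSet`.

    Parameters
    ----------
    table:
        Path (or buffer) of a TSV whose first column holds isoacceptor
        names and whose remaining columns are condition labels; one row
        per isoacceptor.
    anticodon_map:
        Path of the isoacceptor->anticodon TSV, or an already-loaded
        ``{name: TRNASpecies}`` mapping.  Every isoacceptor in the table
        must be covered.
    charging:
        Optional TSV of identical shape giving charged fractions.
    reference_condition:
        Label of the reference pool; defaults to the first column.
    """
    species = (
        anticodon_map
        if isinstance(anticodon_map, Mapping)
        else read_anticodon_map(anticodon_map)
    )
    df = pd.read_csv(table, sep="\t", comment="#", index_col=0)
    unknown = [n for n in df.index if n not in species]
    if unknown:
        raise ValueError(
            f"isoacceptor(s) missing from the anticodon map: {', '.join(map(str, unknown))}"
        )
    charge_df = None
    if charging is not None:
        charge_df = pd.read_csv(charging, sep="\t", comment="#", index_col=0)
        if list(charge_df.index) != list(df.index) or list(charge_df.columns) != list(df.columns):
            raise ValueError("charging table must have the same rows and columns as the pool table")
    pools = []
    for cond in df.columns:
        conc = df[cond].astype(float).to_dict()
        frac = charge_df[cond].astype(float).to_dict() if charge_df is not None else None
        pools.append(TRNAPool(condition=str(cond), concentration=conc, charged_fraction=frac))
    ref = reference_condition if reference_condition is not None else str(df.columns[0])
    used = {n: species[n] for n in df.index}
    return ConditionSet(reference_condition=ref, pools=pools, species=used)


def write_pool_table(cs: ConditionSet, table, charging=None) -> None:
    """Write a ConditionSet back to TSV (inverse of :func:`read_pool_table`)."""
    names = sorted(cs.pools[0].species_names)
    conc = pd.DataFrame(
        {p.condition: [p.concentration[n] for n in names] for p in cs.pools}, index=names
    )
    conc.index.name = "isoacceptor"
    conc.to_csv(table, sep="\t")
    if charging is not None:
        if any(p.charged_fraction is None for p in cs.pools):
            raise ValueError("cannot write charging table: pools carry no charged fractions")
        frac = pd.DataFrame(
            {p.condition: [p.charged_fraction[n] for n in names] for p in cs.pools}, index=names
        )
        frac.index.name = "isoacceptor"
        frac.to_csv(charging, sep="\t")


# ---------------------------------------------------------------------------
# Pool transformations
# ---------------------------------------------------------------------------

def split_grouped_isoacceptors(pool: TRNAPool, ratios: Mapping) -> TRNAPool:
    """Split collectively-measured isoacceptors into individual species.

    Some measurement sets report two isoacceptors as one value (for
    *E. coli*: Gly1+Gly2 and Ile1+Ile2); the combined value is divided
    according to the ratio of gene copy numbers (Gly1:Gly2 = 1:1,
    Ile1:Ile2 = 3:1).

    ``ratios`` maps the grouped row name to ``(member_names, proportions)``
    where the proportions sum to 1.  The pool total is conserved to
    within one float rounding.
    """
    conc = dict(pool.concentration)
    frac = dict(pool.charged_fraction) if pool.charged_fraction is not None else None
    for group, (members, props) in ratios.items():
        if group not in conc:
            raise KeyError(f"grouped isoacceptor {group!r} not in pool")
        if len(members) != len(props):
            raise ValueError(f"{group!r}: {len(members)} members but {len(props)} proportions")
        s = float(sum(props))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"{group!r}: proportions sum to {s}, expected 1")
        value = conc.pop(group)
        # Largest-proportion member is defined by subtraction so the
        # members re-sum to the grouped value up to one final rounding.
        parts = [value * p for p in props]
        biggest = max(range(len(props)), key=props.__getitem__)
        parts[biggest] = value - sum(v for i, v in enumerate(parts) if i != biggest)
        for m, v in zip(members, parts):
            conc[m] = v
        if frac is not None and group in frac:
            gf = frac.pop(group)
            for m in members:
                frac[m] = gf
    return TRNAPool(condition=pool.condition, concentration=conc, charged_fraction=frac)


def effective_availability(charging_pool: TRNAPool, reference_pool: TRNAPool) -> TRNAPool:
    """Charged availability: charged fraction times reference concentration.

    Emulates how absolute availabilities are obtained from a charging
    time course: each species' charged fraction under the perturbed
    condition multiplies its concentration under the reference condition
    (the standard growth rate).  The result carries no charged-fraction
    field — it *is* the charged amount.
    """
    if charging_pool.charged_fraction is None:
        raise ValueError(f"pool {charging_pool.condition!r} has no charged fractions")
    if charging_pool.species_names != reference_pool.species_names:
        missing = charging_pool.species_names ^ reference_pool.species_names
        raise ValueError(f"species mismatch between pools: {sorted(missing)}")
    conc = {
        name: charging_pool.charged_fraction[name] * reference_pool.concentration[name]
        for name in reference_pool.concentration
    }
    return TRNAPool(condition=charging_pool.condition, concentration=conc)


# ---------------------------------------------------------------------------
# Bundled tables
# ---------------------------------------------------------------------------

def bundled_path(filename: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(resources.files("codonflux.data") / filename)


def ecoli_anticodon_map() -> dict:
    """The bundled *E. coli* isoacceptor->anticodon table (editable TSV)."""
    return read_anticodon_map(bundled_path("ecoli_anticodons.tsv"))
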