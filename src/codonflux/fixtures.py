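"""Deterministic synthetic fixtures: pools, perturbations and CDS sets.

Two experimental regimes are emulated:

* *growth-rate-like* shifts — every isoacceptor's concentration scales
  by (nearly) the same factor as growth slows, so codon rates change
  uniformly;
* *starvation-like* shifts — the charged fractions of a targeted
  amino acid's isoacceptors collapse while the rest of the pool is only
  mildly affected, producing heterogeneous rate changes.  The default
  leucine schedule hits the minor isoacceptors (readers of the rare
  CUU/CUC/CUA codons) harder than the major ones, the differential
  pattern starvation measurements show.

The bundled toy organism has 8 isoacceptors chosen so that every wobble
pairing kind (and the CGA:ACG override) is exercised at least once, and
its concentrations are solved so that the "sensitive" codon triple
CUU/CUC/CUA and the "robust" triple CUG/UUA/UUG have exactly equal
summed expected times under the reference pool.  Leucine-twin gene
pairs carry the same amino-acid sequence and differ only in which
synonym triple encodes their leucines, giving a clean sensitive/robust
contrast.

Everything is a pure function of a :class:`FixtureSpec` (seed
mandatory): the same spec yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .codon_rates import SENSE_CODONS, STOP_CODONS, _COMPLEMENT, build_recognition_map
from .profiles import CodingSequence
from .trna_io import ConditionSet, TRNAPool, TRNASpecies, effective_availability

__all__ = [
    "FixtureSpec",
    "UniformScale",
    "TargetedCharging",
    "toy_species",
    "toy_pool",
    "toy_growth_conditions",
    "toy_starvation_conditions",
    "toy_readable_codons",
    "make_pool",
    "perturb",
    "make_cds_set",
    "leucine_twins",
    "DEFAULT_GROWTH_FACTORS",
    "DEFAULT_STARVATION_SCHEDULE",
]


@dataclass(frozen=True)
class UniformScale:
    """Growth-rate-like perturbation: all concentrations times a factor per condition."""

    factors: Mapping[str, float]  # condition label -> factor

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", dict(self.factors))
        for cond, k in self.factors.items():
            if k < 0:
                raise ValueError(f"{cond}: negative scale factor {k}")


@dataclass(frozen=True)
class TargetedCharging:
    """Starvation-like perturbation: charged fractions per condition per species.

    ``schedule`` maps condition label -> {species name -> charged
    fraction in [0, 1]}; species absent from a condition's entry stay
    fully charged.
    """

    schedule: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "schedule", {c: dict(m) for c, m in self.schedule.items()}
        )
        for cond, m in self.schedule.items():
            for sp, f in m.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{cond}/{sp}: charged fraction {f} outside [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Everything a generator run depends on; the seed fixes all randomness."""

    seed: int
    n_species: int = 8
    n_genes: int = 12
    gene_length_range: Tuple[int, int] = (40, 90)  # translated codons
    codon_bias: Optional[Mapping[str, float]] = None
    perturbation: Optional[Union[UniformScale, TargetedCharging]] = None

    def __post_init__(self) -> None:
        if self.codon_bias is not None:
            bias = dict(self.codon_bias)
            if any(w < 0 for w in bias.values()) or not any(w > 0 for w in bias.values()):
                raise ValueError("codon bias weights must be nonnegative and not all zero")
            object.__setattr__(self, "codon_bias", bias)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Toy organism
# ---------------------------------------------------------------------------

def toy_species() -> Tuple[TRNASpecies, ...]:
    """8 isoacceptors covering all nine pairing kinds plus the CGA override."""
    return (
        TRNASpecies("Met", "M", "CAU"),                          # AUG       C34:G3
        TRNASpecies("Ile2", "I", "CAU", modification="lysidine"),  # AUA     L34:A3
        TRNASpecies("Leu1", "L", "CAG"),                         # CUG       C34:G3
        TRNASpecies("Leu2", "L", "GAG"),                         # CUC/CUU   G34:C3, G34:U3
        TRNASpecies("Leu3", "L", "UAG"),                         # CUA/CUG   U34:A3, U34:G3
        TRNASpecies("Leu5", "L", "UAA"),                         # UUA/UUG   U34:A3, U34:G3
        TRNASpecies("Arg2", "R", "ACG"),                         # CGU/CGC/CGA  A34:U3, I34:C3, I34:A3
        TRNASpecies("Gly2", "G", "UCC"),                         # GGA/GGG   U34:A3, U34:G3
    )


# Reference concentrations (opaque units).  Two values are solved rather
# than chosen: Leu1 so that the sensitive triple CUU/CUC/CUA and the
# robust triple CUG/UUA/UUG have exactly equal sum(1/W), i.e. equal
# summed expected times under the reference pool; and Arg2 so that the
# Gly2 species' adaptiveness multiplicity (sum of 1-s over the codons it
# reads) equals the pool-wide ratio sum(W)/sum(conc).  The latter makes
# any change of the Gly2 availability leave every non-Gly codon's rate
# unchanged in exact arithmetic (the normalizer is invariant), so genes
# lacking GGA/GGG have sensitivity exactly zero under a pure Gly2
# perturbation.
_C_MET, _C_ILE2, _C_LEU2, _C_LEU3, _C_LEU5, _C_GLY2 = (
    180.0, 40.0, 270.0, 100.0, 412.5, 220.0,
)

# adaptiveness multiplicity per species under the default s-values
_MULT = {
    "Met": 1.0,                   # AUG (C34:G3)
    "Ile2": 1.0 - 0.89,           # AUA (L34:A3)
    "Leu1": 1.0,                  # CUG (C34:G3)
    "Leu2": 1.0 + (1.0 - 0.41),   # CUC + CUU
    "Leu3": 1.0 + (1.0 - 0.68),   # CUA + CUG
    "Leu5": 1.0 + (1.0 - 0.68),   # UUA + UUG
    "Arg2": 1.0 + (1.0 - 0.28) + (1.0 - 0.9172),  # CGU + CGC + CGA(override)
    "Gly2": 1.0 + (1.0 - 0.68),   # GGA + GGG
}


def _solve_leu1() -> float:
    # sensitive: W(CUU)=0.59*c_Leu2, W(CUC)=c_Leu2, W(CUA)=c_Leu3
    lhs = (1.0 / 0.59 + 1.0) / _C_LEU2 + 1.0 / _C_LEU3
    # robust: W(UUA)=c_Leu5, W(UUG)=0.32*c_Leu5, W(CUG)=c_Leu1+0.32*c_Leu3
    rest = (1.0 + 1.0 / 0.32) / _C_LEU5
    return 1.0 / (lhs - rest) - 0.32 * _C_LEU3


_C_LEU1 = _solve_leu1()


def _solve_arg2() -> float:
    # require sum_j c_j * (m_Gly2 - m_j) = 0; the Gly2 term vanishes, so
    # c_Arg2 = sum_{j not in {Arg2, Gly2}} c_j (m_Gly2 - m_j) / (m_Arg2 - m_Gly2)
    target = _MULT["Gly2"]
    fixed = {
        "Met": _C_MET, "Ile2": _C_ILE2, "Leu1": _C_LEU1,
        "Leu2": _C_LEU2, "Leu3": _C_LEU3, "Leu5": _C_LEU5,
    }
    num = sum(c * (target - _MULT[name]) for name, c in fixed.items())
    return num / (_MULT["Arg2"] - target)


_C_ARG2 = _solve_arg2()


def toy_pool(condition: str = "ref") -> TRNAPool:
    """Reference pool of the toy organism (balanced leucine triples)."""
    return TRNAPool(
        condition=condition,
        concentration={
            "Met": _C_MET,
            "Ile2": _C_ILE2,
            "Leu1": _C_LEU1,
            "Leu2": _C_LEU2,
            "Leu3": _C_LEU3,
            "Leu5": _C_LEU5,
            "Arg2": _C_ARG2,
            "Gly2": _C_GLY2,
        },
    )


# Growth regime: moderate uniform slowdown, deepest condition at half
# the reference availability (codon rates halve, times double).
DEFAULT_GROWTH_FACTORS: Dict[str, float] = {
    "mu2.5": 1.0,
    "mu1.6": 0.85,
    "mu1.07": 0.7,
    "mu0.7": 0.6,
    "mu0.4": 0.5,
}

# Starvation regime: the minor Leu isoacceptors (CUU/CUC/CUA readers)
# collapse far more than the major ones (CUG/UUA/UUG readers); most
# other species show a broad transient dip at t17.
DEFAULT_STARVATION_SCHEDULE: Dict[str, Dict[str, float]] = {
    "t0": {},
    "t2": {"Leu2": 0.08, "Leu3": 0.08, "Leu1": 0.7, "Leu5": 0.7},
    "t7": {"Leu2": 0.05, "Leu3": 0.05, "Leu1": 0.6, "Leu5": 0.6, "Met": 0.95, "Ile2": 0.95},
    "t17": {
        "Leu2": 0.04, "Leu3": 0.04, "Leu1": 0.5, "Leu5": 0.5,
        "Met": 0.6, "Ile2": 0.6, "Arg2": 0.65, "Gly2": 0.65,
    },
    "t32": {"Leu2": 0.05, "Leu3": 0.05, "Leu1": 0.65, "Leu5": 0.65, "Met": 0.9, "Ile2": 0.9},
}


def toy_growth_conditions() -> ConditionSet:
    """Uniform-scaling condition set over the toy pool (reference mu2.5)."""
    spec = FixtureSpec(seed=0, perturbation=UniformScale(DEFAULT_GROWTH_FACTORS))
    cs = perturb(toy_pool("mu2.5"), spec)
    return ConditionSet(
        reference_condition="mu2.5",
        pools=cs.pools,
        species={sp.name: sp for sp in toy_species()},
    )


def toy_starvation_conditions() -> ConditionSet:
    """Targeted-charging condition set over the toy pool (reference t0)."""
    spec = FixtureSpec(seed=0, perturbation=TargetedCharging(DEFAULT_STARVATION_SCHEDULE))
    cs = perturb(toy_pool("t0"), spec)
    return ConditionSet(
        reference_condition="t0",
        pools=cs.pools,
        species={sp.name: sp for sp in toy_species()},
    )


def toy_readable_codons() -> Tuple[str, ...]:
    """Sense codons with at least one recognizer in the toy organism."""
    rec = build_recognition_map(toy_species())
    return tuple(c for c in SENSE_CODONS if rec[c])


# ---------------------------------------------------------------------------
# Random pools and perturbations
# ---------------------------------------------------------------------------

_GENETIC_CODE = None


def _genetic_code() -> Mapping[str, str]:
    global _GENETIC_CODE
    if _GENETIC_CODE is None:
        from Bio.Data.CodonTable import unambiguous_rna_by_id

        _GENETIC_CODE = dict(unambiguous_rna_by_id[11].forward_table)
    return _GENETIC_CODE


def _random_species(rng: np.random.Generator, n: int) -> List[TRNASpecies]:
    """Random isoacceptors with anticodons whose Watson-Crick codon is sense."""
    code = _genetic_code()
    out: List[TRNASpecies] = []
    while len(out) < n:
        ac = "".join(rng.choice(list("ACGU"), size=3))
        wc_codon = "".join(_COMPLEMENT[b] for b in reversed(ac))
        if wc_codon in STOP_CODONS:
            continue
        out.append(TRNASpecies(f"Sp{len(out) + 1}", code[wc_codon], ac))
    return out


def make_pool(spec: FixtureSpec) -> TRNAPool:
    """Seed-reproducible random pool of ``spec.n_species`` isoacceptors.

    For ``n_species <= 8`` the toy organism's species identities are
    used (so every pairing kind is exercised); larger pools append
    random species.  Concentrations are lognormal around ~100.
    """
    rng = spec.rng()
    base = list(toy_species())[: spec.n_species]
    if spec.n_species > len(base):
        base += _random_species(rng, spec.n_species - len(base))
    conc = {sp.name: float(rng.lognormal(mean=np.log(100.0), sigma=0.6)) for sp in base}
    return TRNAPool(condition=f"seed{spec.seed}", concentration=conc)


def perturb(pool: TRNAPool, spec: FixtureSpec) -> ConditionSet:
    """Expand a single pool into a multi-condition set.

    Uniform mode multiplies every concentration by the per-condition
    factor.  Targeted mode attaches the scheduled charged fractions and
    converts them to charged availabilities against the input pool
    (reference concentration times charged fraction).
    """
    pert = spec.perturbation
    if pert is None:
        raise ValueError("FixtureSpec carries no perturbation")
    pools: List[TRNAPool] = []
    if isinstance(pert, UniformScale):
        for cond, k in pert.factors.items():
            pools.append(pool.scaled(k, condition=cond))
        reference = pool.condition if pool.condition in pert.factors else pools[0].condition
    elif isinstance(pert, TargetedCharging):
        for cond, fractions in pert.schedule.items():
            unknown = set(fractions) - pool.species_names
            if unknown:
                raise ValueError(f"{cond}: unknown species {sorted(unknown)}")
            charged = {name: fractions.get(name, 1.0) for name in pool.concentration}
            charging_pool = TRNAPool(
                condition=cond,
                concentration=pool.concentration,
                charged_fraction=charged,
            )
            pools.append(effective_availability(charging_pool, pool))
        reference = pool.condition if pool.condition in pert.schedule else pools[0].condition
    else:
        raise TypeError(f"unknown perturbation type {type(pert).__name__}")
    return ConditionSet(reference_condition=reference, pools=pools)


# ---------------------------------------------------------------------------
# CDS generation
# ---------------------------------------------------------------------------

_SENSITIVE_LEU = ("CUU", "CUC", "CUA")
_ROBUST_LEU = ("CUG", "UUA", "UUG")
_TWIN_BODY = ("CGU", "CGC", "GGA", "GGG")  # non-Leu alphabet of the twin pair


def leucine_twins(
    rng: np.random.Generator,
    length: int = 62,
    window: int = 19,
) -> Tuple[CodingSequence, CodingSequence]:
    """A sensitive/robust gene pair differing only at synonymous Leu sites.

    Both genes carry the same amino-acid sequence; every leucine of the
    sensitive twin uses CUU/CUC/CUA (cycling) and of the robust twin
    CUG/UUA/UUG.  Leu positions are placed in the window-interior of the
    sequence (at least ``window - 1`` codons from either terminus) in a
    count divisible by 3, so that with the balanced toy pool the two
    genes have identical mean smoothed times under the reference
    condition.
    """
    margin = window - 1
    lo, hi = margin, length - margin - 1
    if hi - lo < 8:
        raise ValueError(f"length {length} too short for window {window}")
    leu_positions = list(range(lo, hi + 1, 3))
    leu_positions = leu_positions[: 3 * (len(leu_positions) // 3)]
    if not leu_positions:
        raise ValueError("no room for leucine positions")
    body = rng.choice(_TWIN_BODY, size=length).tolist()
    body[0] = "AUG"
    sens, rob = body.copy(), body.copy()
    for i, pos in enumerate(leu_positions):
        sens[pos] = _SENSITIVE_LEU[i % 3]
        rob[pos] = _ROBUST_LEU[i % 3]
    stop = "UAA"
    return (
        CodingSequence(id="twinL_sensitive", nucleotides="".join(sens) + stop, strict=False),
        CodingSequence(id="twinL_robust", nucleotides="".join(rob) + stop, strict=False),
    )


def make_cds_set(spec: FixtureSpec) -> List[CodingSequence]:
    """Random CDS set over the toy organism's readable codons.

    ``spec.n_genes`` random genes are drawn from ``spec.codon_bias``
    (default: uniform over the toy-readable codons with AUA
    down-weighted, as rare codons are in real genomes), followed by the
    leucine-twin pair.  Every gene starts with AUG, contains no internal
    stops and ends with an appended UAA stop.
    """
    rng = spec.rng()
    if spec.codon_bias is not None:
        alphabet = [c for c, w in spec.codon_bias.items() if w > 0 and c not in STOP_CODONS]
        weights = np.array([spec.codon_bias[c] for c in alphabet], dtype=float)
    else:
        alphabet = list(toy_readable_codons())
        weights = np.array([0.1 if c == "AUA" else 1.0 for c in alphabet])
    weights = weights / weights.sum()
    lo, hi = spec.gene_length_range
    genes: List[CodingSequence] = []
    for i in range(spec.n_genes):
        n = int(rng.integers(lo, hi + 1))
        codons = ["AUG"] + rng.choice(alphabet, size=n - 1, p=weights).tolist()
        genes.append(
            CodingSequence(
                id=f"synth{i + 1:03d}", nucleotides="".join(codons) + "UAA", strict=False
            )
        )
    genes.extend(leucine_twins(rng))
    return genes
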