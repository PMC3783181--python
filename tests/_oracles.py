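"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive everything with literal nested loops and
their own wobble table, sharing no code path with the package.
"""

import itertools
import math

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_STOPS = {"UAA", "UAG", "UGA"}

# Literal wobble table: anticodon-34 base -> [(codon-3' base, pairing kind)].
_WOBBLE_PLAIN = {
    "A": [("U", "A34:U3")],
    "G": [("C", "G34:C3"), ("U", "G34:U3")],
    "U": [("A", "U34:A3"), ("G", "U34:G3")],
    "C": [("G", "C34:G3")],
}
_INOSINE_EXTRA = [("C", "I34:C3"), ("A", "I34:A3")]


def oracle_recognizers(species):
    """codon -> list of (species name, anticodon, kind), by exhaustive check."""
    table = {}
    for codon in ("".join(p) for p in itertools.product("ACGU", repeat=3)):
        if codon in _STOPS:
            continue
        recs = []
        for sp in species:
            ac = sp.anticodon
            # positions 35/36 must be Watson-Crick with codon positions 2/1
            if _COMP[ac[1]] != codon[1] or _COMP[ac[2]] != codon[0]:
                continue
            if sp.modification == "lysidine":
                if codon[2] == "A":
                    recs.append((sp.name, ac, "L34:A3"))
                continue
            pairs = list(_WOBBLE_PLAIN[ac[0]])
            if ac[0] == "A" and sp.inosine34:
                pairs = pairs + _INOSINE_EXTRA
            for third, kind in pairs:
                if codon[2] == third:
                    recs.append((sp.name, ac, kind))
        # exceptions, applied literally
        if codon == "AUA":
            recs = [r for r in recs if r[2] == "L34:A3"]
        if codon == "AUG":
            aa = {sp.name: sp.amino_acid for sp in species}
            recs = [r for r in recs if aa[r[0]] == "M" and r[2] == "C34:G3"]
        table[codon] = recs
    return table


def oracle_rates(pool, species, s_values, overrides):
    """Literal adaptiveness + normalization: returns (W, r, t) dicts."""
    rec = oracle_recognizers(species)
    W = {}
    for codon, recs in rec.items():
        w = 0.0
        for name, ac, kind in recs:
            s = overrides.get((codon, ac), s_values[kind])
            w += (1.0 - s) * pool.concentration[name]
        W[codon] = w
    total_W = sum(W.values())
    total_conc = sum(pool.concentration.values())
    r, t = {}, {}
    for codon, w in W.items():
        if w > 0:
            r[codon] = w / total_W * total_conc
            t[codon] = 1.0 / r[codon]
        else:
            t[codon] = math.inf
    return W, r, t


def oracle_smooth(values, window):
    """O(n*w) centered mean with boundary truncation."""
    half = window // 2
    n = len(values)
    out = []
    for j in range(n):
        lo, hi = max(0, j - half), min(n - 1, j + half)
        chunk = values[lo : hi + 1]
        out.append(sum(chunk) / len(chunk))
    return out


def oracle_runs(below):
    """(run count, max run length) of maximal True runs, by linear scan."""
    count, best, cur = 0, 0, 0
    for b in below:
        if b:
            cur += 1
            if cur == 1:
                count += 1
            best = max(best, cur)
        else:
            cur = 0
    return count, best
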