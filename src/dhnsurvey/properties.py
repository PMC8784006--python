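"""Physico-chemical protein properties: molecular weight, pI, GC content.

Molecular weights use average (not monoisotopic) residue masses plus one
water, matching the ProtParam convention.  The isoelectric point is solved by
bisection on the Henderson-Hasselbalch net charge over the termini and the
D, E, C, Y, H, K, R side chains with the Bjellqvist pKa set (the table behind
ExPASy ProtParam), including its terminal-residue-specific pKa adjustments.
Cysteines are treated as free; no disulfide correction is applied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.SeqUtils import gc_fraction, molecular_weight as _bio_mw

# Bjellqvist pKa values as tabulated by ExPASy ProtParam: charged side chains,
# free termini, and adjusted terminal pKas for specific first/last residues.
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}

_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
_NUCLEOTIDES = frozenset("ACGTN")


@dataclass(frozen=True)
class ProteinProperties:
    """The survey-table property columns for one gene."""

    aa_len: int
    mw_kda: float
    pi: float
    gc_percent: float
    bp_len: int


def _check(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - _RESIDUES
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)}")


def molecular_weight(protein: str) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    _check(protein)
    return _bio_mw(protein, seq_type="protein", monoisotopic=False)


def charge_at_ph(protein: str, ph: float) -> float:
    """Net charge of the protein at a given pH under the Bjellqvist model."""
    _check(protein)
    counts = Counter(protein)
    pos = [(PK_NTERMINAL.get(protein[0], POSITIVE_PKS["Nterm"]), 1)]
    pos += [(POSITIVE_PKS[aa], counts[aa]) for aa in ("K", "R", "H")]
    neg = [(PK_CTERMINAL.get(protein[-1], NEGATIVE_PKS["Cterm"]), 1)]
    neg += [(NEGATIVE_PKS[aa], counts[aa]) for aa in ("D", "E", "C", "Y")]
    charge = sum(n / (1.0 + 10.0 ** (ph - pk)) for pk, n in pos)
    charge -= sum(n / (1.0 + 10.0 ** (pk - ph)) for pk, n in neg)
    return charge


def isoelectric_point(
    protein: str, lo: float = 0.0, hi: float = 14.0, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, found by bisection.

    The charge model is monotonically decreasing in pH, so bisection on any
    bracket within (0, 14) converges to the same root; iteration stops when
    ``|charge| < tol`` or the bracket is narrower than ``tol``.
    """
    _check(protein)
    if not 0.0 <= lo < hi <= 14.0:
        raise ValueError("bracket must lie within [0, 14]")
    # widen to the full scale if the user bracket does not straddle the root
    if charge_at_ph(protein, lo) < 0:
        lo = 0.0
    if charge_at_ph(protein, hi) > 0:
        hi = 14.0
    # the charge curve can be nearly flat away from ionizable side chains, so
    # the early exit on |charge| uses a much tighter cut than the pH bracket
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        charge = charge_at_ph(protein, mid)
        if abs(charge) < 1e-9:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gc_content(cds: str) -> float:
    """GC percentage of a coding sequence, to 2 decimals; N is excluded from
    the denominator."""
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    bad = set(cds) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)}")
    if set(cds) == {"N"}:
        raise ValueError("CDS contains only N")
    return round(100.0 * gc_fraction(cds, ambiguous="remove"), 2)


def compute_properties(cds: str, protein: str) -> ProteinProperties:
    """All survey-table property columns for one gene."""
    return ProteinProperties(
        aa_len=len(protein),
        mw_kda=round(molecular_weight(protein) / 1000.0, 2),
        pi=round(isoelectric_point(protein), 2),
        gc_percent=gc_content(cds),
        bp_len=len(cds),
    )
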