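"""Average molecular weight, net charge and isoelectric point.

Masses are average (not monoisotopic) residue masses with one water added per
chain, matching the Expasy Compute pI/MW conventions.  The isoelectric point
uses Henderson–Hasselbalch terms with the Bjellqvist pKa set, including the
residue-specific N- and C-terminal pKa corrections, solved by bisection on
pH ∈ [0, 14].
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Average residue masses in Da (amino acid minus water), Expasy-compatible.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01524


@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa values (Bjellqvist defaults, as used by Expasy)."""

    positive: dict[str, float] = field(
        default_factory=lambda: {"K": 10.0, "R": 12.0, "H": 5.98}
    )
    negative: dict[str, float] = field(
        default_factory=lambda: {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    n_term: float = 7.5
    c_term: float = 3.55
    # residue-specific terminal overrides
    n_term_by_residue: dict[str, float] = field(
        default_factory=lambda: {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
        }
    )
    c_term_by_residue: dict[str, float] = field(
        default_factory=lambda: {"D": 4.55, "E": 4.75}
    )


DEFAULT_PKA = PkaSet()


@dataclass(frozen=True)
class PhyschemResult:
    mw_da: float
    mw_kd: float  # rounded to 1 decimal
    pI: float  # rounded to 2 decimals


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None
    return total + WATER_MASS


def substitution_mass_delta(ref_aa: str, alt_aa: str) -> float:
    """Residue-mass change (Da) of a single substitution ref→alt."""
    return AVERAGE_RESIDUE_MASS[alt_aa] - AVERAGE_RESIDUE_MASS[ref_aa]


def net_charge(sequence: str, pH: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Net charge at ``pH`` from Henderson–Hasselbalch terms.

    Positive contributors: N-terminus, H, K, R.  Negative: C-terminus,
    D, E, C, Y.  Monotonically non-increasing in pH.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    counts: dict[str, int] = {}
    for aa in sequence:
        counts[aa] = counts.get(aa, 0) + 1
    nterm_pka = pka.n_term_by_residue.get(sequence[0], pka.n_term)
    cterm_pka = pka.c_term_by_residue.get(sequence[-1], pka.c_term)
    pos = 1.0 / (1.0 + 10.0 ** (pH - nterm_pka))
    for aa, k in pka.positive.items():
        pos += counts.get(aa, 0) / (1.0 + 10.0 ** (pH - k))
    neg = 1.0 / (1.0 + 10.0 ** (cterm_pka - pH))
    for aa, k in pka.negative.items():
        neg += counts.get(aa, 0) / (1.0 + 10.0 ** (k - pH))
    return pos - neg


def isoelectric_point(
    sequence: str, pka: PkaSet = DEFAULT_PKA, tol: float = 0.001
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    lo, hi = 1e-9, 14.0 - 1e-9
    f_lo = net_charge(sequence, lo, pka)
    f_hi = net_charge(sequence, hi, pka)
    if f_lo < 0 or f_hi > 0:
        raise ValueError("net charge does not change sign on (0, 14)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def characterize(sequence: str, pka: PkaSet = DEFAULT_PKA) -> PhyschemResult:
    """MW (Da and kD, 1 decimal) and pI (2 decimals) for one sequence."""
    mw = molecular_weight(sequence)
    pi = isoelectric_point(sequence, pka)
    return PhyschemResult(mw_da=mw, mw_kd=round(mw / 1000.0, 1), pI=round(pi, 2))
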