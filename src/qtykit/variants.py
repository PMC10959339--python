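"""Missense variant parsing, QTY/rQTY direction classification, topological
localization, and summary counts.

Variants arrive as HGVS protein-consequence strings (``p.Ile136Thr``) or
compact one-letter form (``I136T``), with optional annotation columns:
location (TM8 / ECL3 / ICL5 / Intracellular), secondary structure, exposure,
ConSurf conservation grade (1–9), PolyPhen-2 effect category, ClinVar note
and minor allele frequency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

from .codons import min_nt_changes
from .qty import QTY_PAIRS, RQTY_PAIRS
from .topology import CANONICAL_AA, ProteinRecord, RegionLabel, Topology

STRUCTURE_CLASSES = (
    "ALPHA_HELIX", "THREE_TEN_HELIX", "FIVE_HELIX", "BETA_STRAND",
    "LOOP", "COIL", "UNKNOWN",
)
#: structure classes counted as helical in summaries
HELICAL_CLASSES = ("ALPHA_HELIX", "THREE_TEN_HELIX", "FIVE_HELIX")

EFFECTS = ("BENIGN", "POSSIBLY_DAMAGING", "PROBABLY_DAMAGING", "UNKNOWN")

_3TO1 = {k.lower(): v for k, v in protein_letters_3to1.items()}

_COMPACT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")
_HGVS_RE = re.compile(r"^p\.([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


class VariantParseError(ValueError):
    pass


def parse_variant(text: str) -> tuple[str, int, str]:
    """Parse ``I136T`` or ``p.Ile136Thr`` into a (ref, pos, alt) triple."""
    text = text.strip()
    m = _COMPACT_RE.match(text)
    if m:
        ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    else:
        m = _HGVS_RE.match(text)
        if not m:
            raise VariantParseError(f"malformed variant {text!r}")
        try:
            ref = _3TO1[m.group(1).lower()]
            alt = _3TO1[m.group(3).lower()]
        except KeyError as exc:
            raise VariantParseError(
                f"unknown residue name {exc.args[0]!r} in {text!r}"
            ) from None
        pos = int(m.group(2))
    if ref not in CANONICAL_AA or alt not in CANONICAL_AA:
        raise VariantParseError(f"non-canonical residue in {text!r}")
    if pos <= 0:
        raise VariantParseError(f"non-positive position in {text!r}")
    return ref, pos, alt


def validate_against(protein: ProteinRecord, ref_aa: str, pos: int) -> bool:
    """True iff ``protein`` carries ``ref_aa`` at 1-based ``pos``."""
    return protein.residue(pos) == ref_aa


@dataclass(frozen=True)
class DirectionLabel:
    value: str  # QTY | RQTY | OTHER
    single_snv_accessible: bool


def classify_direction(ref_aa: str, alt_aa: str) -> DirectionLabel:
    """QTY (L→Q, I→T, V→T, F→Y), RQTY (Q→L, T→I, T→V, Y→F) or OTHER.

    Accessibility is the codon-space fact: every mapped pair except V↔T is
    one nucleotide change away.
    """
    pair = (ref_aa.upper(), alt_aa.upper())
    if pair in QTY_PAIRS:
        value = "QTY"
    elif pair in RQTY_PAIRS:
        value = "RQTY"
    else:
        value = "OTHER"
    return DirectionLabel(value=value, single_snv_accessible=min_nt_changes(*pair) == 1)


@dataclass
class VariantRecord:
    protein: str
    ref_aa: str
    pos: int
    alt_aa: str
    maf: float | None = None
    location: RegionLabel = field(default_factory=lambda: RegionLabel("UNANNOTATED"))
    structure_class: str = "UNKNOWN"
    exposure: str = "UNKNOWN"  # BURIED | EXPOSED | UNKNOWN
    conservation_grade: int | None = None
    effect: str = "UNKNOWN"
    clinical: str | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues must differ")
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValueError(f"unknown structure class {self.structure_class!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.conservation_grade is not None and not 1 <= self.conservation_grade <= 9:
            raise ValueError("conservation grade must be in 1..9")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError("MAF must be in [0,1]")

    @property
    def direction(self) -> DirectionLabel:
        return classify_direction(self.ref_aa, self.alt_aa)

    @property
    def mutation(self) -> str:
        return f"{self.ref_aa}{self.pos}{self.alt_aa}"


_LOCATION_RE = re.compile(r"^(TM|ECL|ICL)(\d+)$")


def parse_location(text: str, structure_hint: str | None = None) -> RegionLabel:
    """Parse a location string (TM8, ECL3, ICL5, Intracellular, ...) into a
    region label.

    Bare "Intracellular" (a cytoplasmic terminus) resolves to N_TERM when the
    structure column hints an N-coil, otherwise C_TERM.
    """
    text = text.strip()
    m = _LOCATION_RE.match(text.upper())
    if m:
        return RegionLabel(m.group(1), int(m.group(2)))
    low = text.lower()
    if low in ("intracellular", "cytoplasmic"):
        if structure_hint and structure_hint.strip().lower().startswith("n-"):
            return RegionLabel("N_TERM")
        return RegionLabel("C_TERM")
    if low in ("n_term", "n-term", "n-terminus"):
        return RegionLabel("N_TERM")
    if low in ("c_term", "c-term", "c-terminus"):
        return RegionLabel("C_TERM")
    if low in ("", "-", "unannotated", "unknown"):
        return RegionLabel("UNANNOTATED")
    raise VariantParseError(f"unrecognized location {text!r}")


def region_side(label: RegionLabel) -> str:
    """'TM', 'extracellular', 'cytoplasmic' or 'unknown' for count summaries.

    N/C termini of the monoamine transporters are intracellular, so termini
    count to the cytoplasmic side.
    """
    if label.category == "TM":
        return "TM"
    if label.category == "ECL":
        return "extracellular"
    if label.category in ("ICL", "N_TERM", "C_TERM"):
        return "cytoplasmic"
    return "unknown"


_STRUCTURE_ALIASES = {
    "α-helix": "ALPHA_HELIX", "alpha-helix": "ALPHA_HELIX", "a-helix": "ALPHA_HELIX",
    "3/10-helix": "THREE_TEN_HELIX", "310-helix": "THREE_TEN_HELIX",
    "5-helix": "FIVE_HELIX", "pi-helix": "FIVE_HELIX",
    "β-strand": "BETA_STRAND", "beta-strand": "BETA_STRAND", "b-strand": "BETA_STRAND",
    "loop": "LOOP", "n-coil": "COIL", "c-coil": "COIL", "coil": "COIL",
    "-": "UNKNOWN", "": "UNKNOWN",
}

_EFFECT_ALIASES = {
    "benign": "BENIGN",
    "? damaging": "POSSIBLY_DAMAGING", "?damaging": "POSSIBLY_DAMAGING",
    "possibly damaging": "POSSIBLY_DAMAGING",
    "damaging": "PROBABLY_DAMAGING", "probably damaging": "PROBABLY_DAMAGING",
    "-": "UNKNOWN", "": "UNKNOWN",
}


def _norm_structure(text: str) -> str:
    key = str(text).strip().lower()
    if key in _STRUCTURE_ALIASES:
        return _STRUCTURE_ALIASES[key]
    up = str(text).strip().upper()
    if up in STRUCTURE_CLASSES:
        return up
    raise VariantParseError(f"unrecognized structure {text!r}")


def _norm_effect(text: str) -> str:
    key = str(text).strip().lower()
    if key in _EFFECT_ALIASES:
        return _EFFECT_ALIASES[key]
    up = str(text).strip().upper()
    if up in EFFECTS:
        return up
    raise VariantParseError(f"unrecognized effect {text!r}")


def _norm_exposure(text: str) -> str:
    low = str(text).strip().lower()
    if low.startswith("buried"):
        return "BURIED"
    if low.startswith("exposed"):
        return "EXPOSED"
    return "UNKNOWN"


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV (columns: protein, mutation, location, structure,
    exposure, conservation_grade, effect, clinical, maf)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return variants_from_frame(df.fillna(""))


def variants_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    if "protein" not in df.columns or "mutation" not in df.columns:
        raise VariantParseError("variant table needs 'protein' and 'mutation' columns")
    out: list[VariantRecord] = []
    for _, row in df.iterrows():
        ref, pos, alt = parse_variant(str(row["mutation"]))
        structure_raw = str(row.get("structure", ""))
        grade_raw = str(row.get("conservation_grade", "")).strip()
        maf_raw = str(row.get("maf", "")).strip()
        clinical = str(row.get("clinical", "")).strip()
        out.append(
            VariantRecord(
                protein=str(row["protein"]),
                ref_aa=ref,
                pos=pos,
                alt_aa=alt,
                location=parse_location(str(row.get("location", "")), structure_raw),
                structure_class=_norm_structure(structure_raw),
                exposure=_norm_exposure(str(row.get("exposure", ""))),
                conservation_grade=int(grade_raw) if grade_raw not in ("", "-") else None,
                effect=_norm_effect(str(row.get("effect", ""))),
                clinical=clinical if clinical not in ("", "-") else None,
                maf=float(maf_raw) if maf_raw not in ("", "-") else None,
            )
        )
    return out


def load_transporter_variants() -> list[VariantRecord]:
    """The packaged monoamine-transporter QTY/rQTY variant table (transcribed
    gnomAD/ClinVar missense annotations for the seven subject proteins)."""
    ref = resources.files("qtykit.data").joinpath("monoamine_transporter_variants.tsv")
    with resources.as_file(ref) as p:
        return read_variant_table(p)


@dataclass(frozen=True)
class VariantSummary:
    n_total: int
    n_qty: int
    n_rqty: int
    n_other: int
    n_qty_tm: int
    n_benign_qty_tm: int
    n_possibly_damaging_qty_tm: int
    n_probably_damaging_qty_tm: int
    n_helical_qty: int
    n_helical_qty_benign: int
    n_rqty_outside_tm: int
    n_rqty_extracellular: int
    n_rqty_cytoplasmic: int
    n_benign_rqty_outside_tm: int
    n_benign_rqty: int
    pct_qty_tm: float
    pct_benign_qty_tm: float
    pct_rqty_outside_tm: float


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


def summarize(variants: list[VariantRecord]) -> VariantSummary:
    """Direction/topology/effect count summary over a variant set."""
    qty = [v for v in variants if v.direction.value == "QTY"]
    rqty = [v for v in variants if v.direction.value == "RQTY"]
    qty_tm = [v for v in qty if v.location.is_tm]
    helical_qty = [v for v in qty if v.structure_class in HELICAL_CLASSES]
    rqty_out = [v for v in rqty if not v.location.is_tm]
    return VariantSummary(
        n_total=len(variants),
        n_qty=len(qty),
        n_rqty=len(rqty),
        n_other=len(variants) - len(qty) - len(rqty),
        n_qty_tm=len(qty_tm),
        n_benign_qty_tm=sum(v.effect == "BENIGN" for v in qty_tm),
        n_possibly_damaging_qty_tm=sum(v.effect == "POSSIBLY_DAMAGING" for v in qty_tm),
        n_probably_damaging_qty_tm=sum(v.effect == "PROBABLY_DAMAGING" for v in qty_tm),
        n_helical_qty=len(helical_qty),
        n_helical_qty_benign=sum(v.effect == "BENIGN" for v in helical_qty),
        n_rqty_outside_tm=len(rqty_out),
        n_rqty_extracellular=sum(region_side(v.location) == "extracellular" for v in rqty),
        n_rqty_cytoplasmic=sum(region_side(v.location) == "cytoplasmic" for v in rqty),
        n_benign_rqty_outside_tm=sum(v.effect == "BENIGN" for v in rqty_out),
        n_benign_rqty=sum(v.effect == "BENIGN" for v in rqty),
        pct_qty_tm=_pct(len(qty_tm), len(qty)),
        pct_benign_qty_tm=_pct(
            sum(v.effect == "BENIGN" for v in qty_tm), len(qty_tm)
        ),
        pct_rqty_outside_tm=_pct(len(rqty_out), len(rqty)),
    )
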