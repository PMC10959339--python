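"""High-level report builders over the library modules."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import physchem, qty
from .topology import ProteinRecord, Topology
from .variants import VariantRecord, summarize


def run_full_characterization(
    proteins: list[ProteinRecord], topologies: dict[str, Topology]
) -> pd.DataFrame:
    """Per protein: native and QTY-variant pI and MW (kD), TM and overall
    variation percentages — one native row and one variant row each."""
    if not proteins:
        raise ValueError("no proteins to characterize")
    rows = []
    for prot in proteins:
        topo = topologies[prot.accession]
        native = physchem.characterize(prot.sequence)
        variant, events = qty.apply_qty(prot, topo)
        var_chem = physchem.characterize(variant.sequence)
        stats = qty.variation_stats(events, prot, topo)
        rows.append(
            {
                "name": prot.accession,
                "pI": native.pI,
                "mw_kd": native.mw_kd,
                "tm_variation_pct": None,
                "overall_variation_pct": None,
            }
        )
        rows.append(
            {
                "name": variant.accession,
                "pI": var_chem.pI,
                "mw_kd": var_chem.mw_kd,
                "tm_variation_pct": stats.tm_variation_pct,
                "overall_variation_pct": stats.overall_variation_pct,
            }
        )
    return pd.DataFrame(rows)


def run_variant_report(variants: list[VariantRecord]) -> dict:
    """Classified variant table plus the direction/topology summary."""
    table = pd.DataFrame(
        {
            "protein": [v.protein for v in variants],
            "mutation": [v.mutation for v in variants],
            "direction": [v.direction.value for v in variants],
            "single_snv_accessible": [v.direction.single_snv_accessible for v in variants],
            "location": [str(v.location) for v in variants],
            "structure": [v.structure_class for v in variants],
            "effect": [v.effect for v in variants],
        }
    )
    summary = dataclasses.asdict(summarize(variants))
    return {"table": table, "summary": summary}


def write_report(report: dict, out_dir: str | Path, stem: str, seed: int | None = None) -> None:
    """Write a report's table as TSV and its summary as JSON with a metadata
    block recording the package version and seed."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"qtykit_version": __version__, "seed": seed}
    if "table" in report:
        report["table"].to_csv(out / f"{stem}.tsv", sep="\t", index=False)
    payload = {"metadata": meta, "summary": report.get("summary", {})}
    (out / f"{stem}.json").write_text(json.dumps(payload, indent=2))
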