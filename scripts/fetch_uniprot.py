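#!/usr/bin/env python
"""Fetch the seven monoamine-transporter sequences and TM topologies from
UniProt (pinned accessions) into local FASTA + topology TSV files.

Network-dependent helper for users who want to run the full characterization
on the real subjects; never invoked by the test suite.  Downloads are
checksummed so a changed UniProt release is detected rather than silently
consumed.

Usage: python scripts/fetch_uniprot.py --out-dir data/uniprot
"""

from __future__ import annotations

import argparse
import hashlib
import json
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "P23975": "NET",
    "Q01959": "DAT",
    "P31645": "SERT",
    "P54219": "VMAT1",
    "Q05940": "VMAT2",
    "Q16572": "VAChT",
    "Q6NT16": "VPAT",
}

FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
JSON_URL = "https://rest.uniprot.org/uniprotkb/{acc}.json"

KIND_MAP = {
    "Transmembrane": "TM_HELIX",
    "Topological domain:Extracellular": "EXTRACELLULAR",
    "Topological domain:Cytoplasmic": "CYTOPLASMIC",
    "Topological domain:Lumenal": "EXTRACELLULAR",  # vesicular lumen ~ EC side
}


def fetch(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("data/uniprot"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for acc, name in ACCESSIONS.items():
        fasta = fetch(FASTA_URL.format(acc=acc))
        (args.out_dir / f"{acc}.fasta").write_bytes(fasta)
        entry = json.loads(fetch(JSON_URL.format(acc=acc)))
        rows = []
        for feat in entry.get("features", []):
            ftype = feat.get("type")
            desc = feat.get("description", "")
            key = ftype if ftype == "Transmembrane" else f"{ftype}:{desc}"
            kind = KIND_MAP.get("Transmembrane" if ftype == "Transmembrane" else key)
            if kind is None:
                continue
            loc = feat["location"]
            rows.append((kind, loc["start"]["value"], loc["end"]["value"]))
        with open(args.out_dir / f"{acc}.topology.tsv", "w") as fh:
            fh.write("kind\tstart\tend\n")
            for kind, start, end in sorted(rows, key=lambda r: r[1]):
                fh.write(f"{kind}\t{start}\t{end}\n")
        checksums[acc] = {
            "name": name,
            "fasta_sha256": hashlib.sha256(fasta).hexdigest(),
        }
        print(f"fetched {acc} ({name})")
    (args.out_dir / "checksums.json").write_text(json.dumps(checksums, indent=2))


if __name__ == "__main__":
    main()
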