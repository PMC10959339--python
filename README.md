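# qtykit

Membrane proteins such as the monoamine transporters (SERT, DAT, NET, the
vesicular VMAT1/VMAT2/VAChT/VPAT) are hard to study because their
transmembrane (TM) helices are hydrophobic: they aggregate in water and need
detergents at every experimental step. The **QTY code** is a deterministic
design rule that sidesteps this: inside each TM helix, replace the
hydrophobic residues with hydrophilic residues of near-identical side-chain
shape,

```
L → Q    V → T    I → T    F → Y
```

and the protein becomes water-soluble while the helical fold is essentially
preserved. The **reverse QTY code** (Q→L, T→I, Y→F; threonine reverts to
isoleucine, never valine) restores hydrophobicity.

`qtykit` implements the full analysis pipeline around this rule:

- **Design** — apply the QTY/rQTY maps to TM helices given UniProt-style
  topology annotations, and report TM and overall variation percentages.
- **Physicochemistry** — average molecular weight and isoelectric point
  (Bjellqvist pKa set, Henderson–Hasselbalch charge model solved by
  bisection), plus per-substitution mass deltas.
- **Codon space** — single-nucleotide accessibility between amino acids in
  the standard genetic code. Every QTY pair except V↔T is one second-position
  point mutation away (L↔Q and F↔Y transversions, I↔T a transition); V↔T
  needs two consecutive changes in one codon, which is why natural V→T
  missense variants are essentially absent.
- **Natural variants** — parse HGVS/compact missense notation, classify
  QTY/rQTY direction, localize by TM/loop topology, and summarize counts. A
  table of 89 natural QTY-direction variants of the seven human monoamine
  transporters (with structure, exposure, conservation grade, predicted
  effect, ClinVar note and allele frequency annotations) ships with the
  package.
- **Mutation libraries** — exhaustive 19-substitution libraries over chosen
  residues, the fixed QTY-vs-other-polar comparator groups, and median/IQR
  summaries of effect scores in [0, 1].
- **Alignment statistics** — per-column residue frequencies of a QTY pair,
  Spearman ρ between the pair members, and the partial Spearman ρ holding a
  per-column conservation score fixed, with seeded bootstrap CIs.
- **Structure comparison** — CA-based Kabsch superposition and RMSD between
  PDB structure pairs, with optional trimming of termini/loops.
- **Synthetic data** — seeded generators for toy transporters, variant
  tables, score tables, alignments and coordinate sets with planted,
  recoverable structure, so every stage is testable offline.

## Worked example

Classify and summarize the packaged natural-variant table:

```
$ qtykit variants summarize
{
  "n_total": 89,
  "n_qty": 47,
  "n_rqty": 42,
  "n_qty_tm": 29,
  "n_benign_qty_tm": 14,
  "n_helical_qty": 40,
  "n_helical_qty_benign": 16,
  "n_rqty_outside_tm": 25,
  "n_rqty_extracellular": 17,
  "n_rqty_cytoplasmic": 8,
  ...
}
```

Of the 89 natural variants, 47 run in the QTY direction and 42 in reverse;
29 of the 47 (61.7 %) sit inside TM helices, where 14 are predicted benign —
consistent with QTY-type substitutions being unusually well tolerated for
changes at buried hydrophobic positions. Most reverse-direction variants
(25/42) lie outside the membrane.

Codon-space accessibility of the four pairs:

```
$ qtykit codon report
ref  alt  min_nt_changes  single_snv_accessible  positions  base_changes  mut_classes
L    Q    1               True                   [2]        ['U->A']      ['transversion']
I    T    1               True                   [2]        ['U->C']      ['transition']
V    T    2               False                  []         []            []
F    Y    1               True                   [2]        ['U->A']      ['transversion']
```

Design a water-soluble variant of a synthetic 12-TM transporter:

```
$ qtykit synth transporter --seed 5 --hydrophobic-frac 0.8 \
    --out-fasta toy.fasta --out-topology toy.topology.json
$ qtykit qty apply --fasta toy.fasta --topology toy.topology.json \
    --out-fasta toy_qty.fasta --events-tsv events.tsv
TOY5: 203 substitutions, TM 80.56%, overall 53.14%
```

The library API mirrors the CLI (`qtykit.apply_qty`, `qtykit.summarize`,
`qtykit.pair_correlation`, `qtykit.kabsch_superpose`, ...). To run the
characterization on the real transporters, fetch the pinned UniProt
sequences and topologies first (`python scripts/fetch_uniprot.py`); nothing
in the test suite requires network access.

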