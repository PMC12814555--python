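# moclosim

In-silico support for large-scale **Golden Gate / Modular Cloning (MoClo)
campaigns**: simulate many one-pot Type IIS assembly reactions specified in
tabular campaign files, and generate the companion data a cloning campaign
needs — output plasmid maps, a produced-plasmid registry, simulated
verification gels, and equimolar dilution plans.

## Who this is for

Synthetic-biology labs building dozens-to-hundreds of plasmid variants at
once. Each row of a campaign file is one one-pot Golden Gate reaction;
`moclosim` resolves the listed part names against a GenBank plasmid
database through an *iP_mapping* table, predicts every product sequence,
and flags rows that cannot assemble — before any enzyme is pipetted.

## The model

A Type IIS enzyme (BsaI = GGTCTC(1/5), BsmBI, BbsI, SapI, AarI built in)
recognizes a non-palindromic site and cuts at a fixed offset outside it,
leaving a short 5′ overhang (the **fusion site**). For a top-strand site
starting at position *p* with recognition length *m* and spacers *(a/b)*:

```
top cut    = p + m + a          bottom cut = p + m + b
overhang   = seq[top_cut : bottom_cut]        (read 5'→3' on the top strand)
```

A bottom-strand site starting at *q* cuts upstream at `q − b` / `q − a`.
Digestion of a circular plasmid with *k* cuts yields *k* sticky fragments,
each represented as `left_fusion + payload`; length is conserved:
Σ(|payload| + overhang) = plasmid length. Each input plasmid contributes
its unique recognition-free fragment; assembly then chains fragments where
`A.right_fusion == B.left_fusion`. A reaction **succeeds** iff this
directed relation admits exactly one circle using every fragment once;
otherwise it is *incomplete* (unpartnered overhang), *ambiguous*
(duplicated overhang → several products) or *multiple_circles*.

MoClo **typed** systems are modeled as grammars: ordered positions (type
"2" = promoter, …), each optionally pinned to an expected fusion-site
pair; a coherent grammar's fusion chain closes circularly. Composite cells
("`AGA2.tTDH1`") split on the subpart separator.

## Worked example

```python
from moclosim import (DnaMolecule, digest, select_insert_fragment,
                      BUILTIN_TYPE_IIS)

bsai = BUILTIN_TYPE_IIS["BsaI"]
plasmid = DnaMolecule("circ29", "GGTCTCAAATGCCCGCTTTGAGACCTTTT", "circular")
frags = digest(plasmid, bsai)
insert = select_insert_fragment(frags, bsai)
print(len(frags), insert.left_fusion, insert.payload, insert.right_fusion)
```

prints `2 AATG CCC GCTT`: the 29-nt circle carries two inward-facing BsaI
sites cutting at 7/11 and 14/18, releasing the recognition-free part
`AATG|CCC|GCTT` (fusion sites AATG and GCTT) and a backbone that retains
both recognition sites.

A full campaign from the command line (the fixture generator creates a
complete miniature kit — database, mapping, grammar — so this runs
self-contained):

```bash
python -c "
from moclosim import make_kit, make_campaign, BUILTIN_TYPE_IIS
kit = make_kit(3, 2, BUILTIN_TYPE_IIS['BsaI'], seed=1, out_dir='demo')
make_campaign(kit, 6, error_rows=[4], seed=1, path='demo/campaign.csv')"
moclosim simulate demo/campaign.csv --db demo/db --mapping demo/ip_mapping.csv \
    --grammar demo/grammar.yaml --out demo/out
```

prints `5/6 reactions assembled; outputs in demo/out` and exits with code
2 (one row carries an injected typo). `demo/out/` then holds one GenBank
map per assembled plasmid (`oP001.gb` …), `db_produced.csv` registering
the five new plasmids for reuse in later campaigns, `report.txt`,
`summary.json` and `provenance.json`. Add `--gel-enzymes EcoRI`,
`--dilutions stocks.csv` and `--picklist` for gels, dilution plans and a
liquid-handler picklist.

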