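# polyals

Molecular diagnostics for polyploid *Echinochloa* (barnyard grass and
late watergrass), the weeds that dominate herbicide resistance in rice
fields. The package implements, as tested desk-scale computations, the
workflow used to characterise target-site resistance to ALS-inhibiting
herbicides in these allopolyploids:

1. **CAPS-rbcL barcoding** — in-silico PCR plus TasI digestion of the
   chloroplast rbcL marker separates the "red" species group
   (*E. crus-galli*, hexaploid) from the "white" group
   (*E. oryzicola*, tetraploid): only the white haplotype's amplicon
   carries the TasI site and cuts into two bands.
2. **Homoeolog assignment** — cloned *ALS* sequences (each clone one
   molecule) are clustered by p-distance UPGMA; the cluster count
   recovers the per-species copy number (three copies ALS1/ALS2/ALS3
   in the hexaploid, two in the tetraploid), and partial 5'/3' clone
   libraries are assigned to labelled anchor consensuses to estimate
   per-copy sampling proportions.
3. **Resistance-codon calling** — clones are mapped onto standardized
   ALS codon numbering by protein alignment and the watched codons
   122/197/574 are called against the known allele table
   (Ala122→Val/Thr/Asn, Pro197→Ser/Leu, Trp574→Leu).
4. **Allele-specific primer design** — ARMS-style primer pairs whose 3'
   termini sit on copy-diagnostic SNPs (codons 590 and 621), with a
   deliberate third-from-3' mismatch, validated in silico by FokI
   digestion (only the ALS1-class product cuts).
5. **ΔΔCt expression** — relative quantification of ALS1 vs ALS2-3,
   RQ = 2^(−ΔΔCt) with ΔΔCt = (Ct_t − Ct_ref) − (Ct_cal − Ct_ref,cal),
   reference genes averaged (*Rubisco*, *18S*), untreated susceptible
   plants as calibrator.

A seeded synthetic-data module generates every input the pipeline
needs — species template models embedding the published primer
sequences verbatim, clone libraries with truth labels, rbcL barcode
panels, and replicated Ct tables — so the whole analysis is testable
without any downloads. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
from polyals import synthdata
from polyals.barcoding import classify_caps
from polyals.homoeolog import (cluster_clones, derive_anchors,
                               trim_anchors, assign_to_copies)
from polyals.mutations import call_tsr, default_reference

red, white = synthdata.make_species_models(seed=0)
marker = synthdata.caps_rbcl_marker((red, white))
print(marker.group_patterns)
# {'red': (221,), 'white': (87, 134)}     <- white cuts into the 134+87 bands

panel = synthdata.sample_rbcl_panel((red, white), n_per_group=3, seed=1)
print(classify_caps(panel[0], marker))
# red                                      <- each plant called red/white

full = synthdata.sample_clone_library(
    (red, white), synthdata.GeneratorConfig(seed=1, n_clones=30, part="full"))
clusters = cluster_clones(full).clusters
print([len(c) for c in clusters])
# [16, 8, 6]                               <- three ALS copies in the mix
anchors = derive_anchors(clusters, default_reference())
print([a.label for a in anchors])
# ['ALS1', 'ALS2', 'ALS3']

lib3 = synthdata.sample_clone_library(
    (red, white), synthdata.GeneratorConfig(seed=7, n_clones=138, part="3prime"))
asg = assign_to_copies(lib3, trim_anchors(anchors, "3prime"))
print({k: round(v, 3) for k, v in asg.proportions().items()})
# {'ALS1': 0.536, 'ALS2': 0.312, 'ALS3': 0.152}   <- ~55/30/15 mix recovered

clone = next(c for c in lib3 if c.meta["population"] == "45R"
             and c.meta["true_copy"] == "ALS1")
for call in call_tsr(clone, default_reference()):
    print(call.position, call.aa_change, call.edits, call.flag)
# 574 Trp574Leu G→T known-resistance      <- the white-species TSR allele
```

The numbers mean: the CAPS digest separates the species groups; the
full-length clone library clusters into the three gene copies; 53.6% of
the 138 3'-end clones land on ALS1 (the generating mix was 55/30/15, so
the estimate is within binomial sampling noise); and a resistant white
ALS1 clone carries the Trp574Leu substitution, reported in standardized
codon numbering with its G→T nucleotide edit.

The same workflow is scriptable from the shell:

```
polyals run-all --outdir run1 --seed 1
polyals qpcr --ct run1/ct_table.csv --refs Rubisco,18S \
             --calibrator 16S:untreated --out rq.csv
```

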