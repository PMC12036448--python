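# gluconet

Glucuronidation fingerprinting for untargeted LC-MS/MS metabolomics.

Glucuronidation is the phase-2 conjugation that attaches glucuronic acid to
endogenous and xenobiotic metabolites for excretion; gut microbial
β-glucuronidase (GUS) enzymes reverse it, regenerating the active aglycone.
The *glucuronidome* — all glucuronidated metabolites detectable in a sample —
is poorly covered by MS/MS reference libraries, so most conjugates go
unannotated.  `gluconet` detects them from the fragmentation chemistry of the
conjugate moiety itself, independent of library coverage, and is aimed at
metabolomics researchers studying host–microbiome metabolite exchange.

## What it computes

**Pattern filtering.**  In MS/MS, a glucuronide loses the dehydrated
glucuronic-acid moiety (C6H8O6, NL 176.0321 Da; less commonly intact
glucuronic acid C6H10O7, NL 194.0425 Da) and, in negative ESI, yields
glucuronate product ions at *m/z* 113.0244 and 85.0295 (85.0295 = 113.0244 −
CO).  A spectrum is called glucuronidated when

```
(∃ fragment f : |precursor − f − 176.0321| ≤ 0.003  OR  |precursor − f − 194.0425| ≤ 0.003)
AND  ∃ peak at 113.0244 ± 0.003   AND  ∃ peak at 85.0295 ± 0.003
```

with relative-intensity floors (5% on the loss fragment, 3% on the products)
in the "biological" query variants.  Galacturonic-acid conjugates — C6
epimers sharing the same neutral loss — are flagged by their discriminating
high-intensity fragment at *m/z* 115.0038, and decoy-labeled collections give
a query false-discovery rate FDR = FP/(FP+TP).

**Molecular networking.**  Spectra are linked by the modified cosine
(fragments pair directly or shifted by the precursor Δ*m/z*; √intensity
weights, L2-normalized, greedy one-to-one pairing), pruned GNPS-style
(cosine ≥ 0.4, ≥ 3 matched fragments, mutual top-10, components ≤ 100 at the
biological preset).  Pruned edges whose |Δprecursor| matches a conjugation
shift (176.032 / 194.042 / 96.075 ± 0.003 Da, the last being the
glucuronide-vs-sulfate spacing C6H8O6 − SO3) are re-added, and unannotated
glucuronide-flagged nodes adjacent to a library-annotated aglycone *A*
inherit the label "suspect *A* glucuronide".

**Glucuronidome statistics.**  From aligned feature tables: per-sample
richness above matrix-specific noise thresholds; two-group Poisson tests on
richness counts (Wald, SE = √(1/Σa + 1/Σb)); per-feature differential
abundance (log2 areas, Welch *t*, Benjamini–Hochberg; significant at
q < 0.1 and |log2FC| > 1); Bray–Curtis distances with PCoA; and
cross-matrix feature matching by m/z + RT + MS/MS similarity.

**Synthetic data.**  A seeded generator produces labeled conjugate spectra
(glucuronides, galacturonide decoys, sulfates, aglycones, noise) and
three-matrix feature tables with planted colonization shifts, so the whole
pipeline is testable offline.

## Worked example

```python
from gluconet import (SynthConfig, default_queries, estimate_fdr,
                      make_labeled_dataset)

collection, labels = make_labeled_dataset(
    SynthConfig(seed=1),
    class_counts={"glucuronide": 200, "galacturonide_decoy": 100,
                  "aglycone": 200, "sulfate": 0, "noise": 0})
full = default_queries()["neg_biological"]
for name, q, veto in [("NL only", full.without_products(), False),
                      ("NL + products", full, False),
                      ("NL + products + veto", full, True)]:
    rep = estimate_fdr(collection, labels, q, veto=veto)
    print(f"{name:22s} FDR {100*rep.fdr:5.1f}%  sensitivity {rep.sensitivity:.2f}")
```

prints

```
NL only                FDR  33.3%  sensitivity 1.00
NL + products          FDR  26.7%  sensitivity 1.00
NL + products + veto   FDR   0.0%  sensitivity 1.00
```

The neutral-loss-only query accepts every galacturonide decoy (they are
isomers of glucuronides); requiring the glucuronate product ions drops the
decoys that do not fragment to the full product series; vetoing spectra
with a strong 115.0038 peak removes the rest — all without losing a single
true glucuronide.  The `examples/` directory has one narrative script per
capability (pattern filtering, decoy FDR, networking + suspect annotation,
feature-table statistics), and a thin CLI (`gluconet simulate|filter|
network|annotate|summarize`) wraps the same functions for shell use.

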