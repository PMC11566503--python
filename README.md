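# biomon

A Python library and CLI for freshwater-biomonitoring workflows: it
harmonizes heterogeneous-resolution community data against a taxonomic
reference and computes diversity indices, sensitivity-score biotic indices
(BMWP/ASPT, WHPT, LIFE, PSI/EPSI, IBMR, biocontamination, ...) and
fuzzy-trait functional indices (FRic/FDis/FEve, Rao's Q, redundancy, CWM,
CSI), with full traceability of which taxa contributed to each value.

## Features

- **Taxonomy** — validate reference datasets (`validate_reference`,
  `ref_from_tree`), match community names with misspelling suggestions
  (`as_biomonitor`, Damerau–Levenshtein ranked candidates, never silent
  auto-correction), and aggregate abundances to every rank
  (`aggregate_taxa`). Indices can then be computed at any taxonomic level
  via `tax_lev`.
- **Diversity** — richness, Shannon, Simpson family, Pielou,
  Berger–Parker, Margalef, Menhinick, Brillouin, McIntosh, Fisher's alpha;
  undefined cases return NaN plus a machine-readable flag.
- **Biotic indices** — pluggable `ScoreTable`s (scalar scores,
  abundance-class score vectors, group matrices, weights, CS/E pairs),
  composite-family rules, log-10 abundance classes, and `trace_b=True`
  traces from which every value is exactly recomputable
  (`recompute_from_trace`).
- **Traits** — `assign_traits` / `manage_traits` / `average_traits` /
  `sample_traits` across taxonomic levels, plus `zerodist_rm` and
  `add_bias_to_traits` for identical-profile ties.
- **Functional** — per-block Gower dissimilarity on fuzzy-coded traits,
  PCoA with Cailliez/Lingoes/square-root/quasi-Euclidean corrections,
  trait-space quality by distance correlation, eigenvalue r² and mean
  squared deviation (`select_pcoa_axes`), and the functional index suite.
- **Indicators & plot data** — IndVal with a seeded permutation test and
  three serializable plot structures (indicator-taxa Sankey, rank
  prevalence, cluster-ordered composition). No graphics are rendered.
- **Fixtures** — seeded synthetic generators for references, mixed-
  resolution log-series communities, fuzzy trait tables and every score
  table kind, so the whole package is testable offline.

Published national score tables and trait databases are not redistributed;
load your own via the documented CSV/JSON formats (`biomon.io`).

## CLI

```bash
biomon fixtures --preset demo --seed 0 --out demo/        # synthetic workspace
biomon import --community demo/community.csv --reference demo/reference.csv \
    --out demo/agg.json --report demo/report.json
biomon calc --index aspt --in demo/agg.json --scores demo/scores_bmwp.csv \
    --trace demo/trace.json --out demo/aspt.csv
biomon calc --index shannon --tax-lev Family --in demo/agg.json --out demo/shannon.csv
biomon functional space --in demo/agg.json --traits demo/traits.csv \
    --blocks demo/trait_blocks.json --correction cailliez --out demo/space.json
biomon indval --in demo/agg.json --groups groups.csv --out demo/indval.csv
biomon plotdata sankey --in demo/agg.json --cluster-k 2 --out demo/sankey.json
biomon show-scores --index aspt
```

Validation/argument errors exit with status 2; unknown index names print
the full registry (34 indices, `biomon.list_indices()`).

## Library quick start

```python
import biomon
from biomon.fixtures import demo_workspace

ws = demo_workspace(seed=0)
tagged, report = biomon.as_biomonitor(ws["community"], ws["reference"])
agg = biomon.aggregate_taxa(tagged)

biomon.shannon(agg, tax_lev="Taxa").values
res = biomon.aspt(agg, ws["scores"]["bmwp"], trace_b=True)
res.values, res.trace
```

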