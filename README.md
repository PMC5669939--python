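# evcargo

Profiling the small-RNA cargo of extracellular vesicles (EVs). Tumour cell
lines shed membrane-bound vesicles whose RNA content — miRNAs, their sequence
variants (isomiRs), and snoRNAs — is cell-type specific and a candidate
source of circulating biomarkers. `evcargo` implements the computational side
of such a study as a tested, reusable pipeline:

- **read assignment** — each small-RNA read is placed, ungapped, against
  canonical mature miRNAs on their hairpins, recording 5'/3' end offsets,
  internal substitutions and non-templated 3' tails;
- **isomiR classification** — assignments collapse into isomiR identities
  classified into six variant categories (canonical, 5'-end only, 3'-end
  only, both ends, substitution only, substitution + end) with a
  deterministic, invertible naming grammar;
- **quantification** — percent-of-total expression, group-mean thresholding
  (default 0.05% in at least one cell line), top-N shared/unique cargo
  profiles, cumulative top-N share, isomiR fraction;
- **clustering** — log2-transformed profiles, 1 − Pearson distance, average
  linkage, with a replicate-coherence test (do biological replicates form
  their own clade?);
- **snoRNA profiling** — box-class (C/D, H/ACA, scaRNA) composition of the
  most abundant snoRNAs seen as full-length molecules (whole-transcriptome
  style libraries) versus short fragments (small-RNA libraries), and the
  overlap between the two views;
- **EV biophysics** — the nanoplasmonic aggregation index AI = A₅₁₉/A₆₅₀
  from a UV-Vis spectrum, and the count-weighted mean EV diameter from an
  AFM size histogram (objects < 30 nm excluded);
- **synthetic data** — a generator producing references, group-structured
  abundances and reads under a parameterized isomiR process, with per-read
  ground truth, so every stage is verifiable by parameter recovery.

## The assignment model

A read r placed on mature m (occupying hairpin positions `[start, end)`)
at 5' offset δ₅ determines the 3' offset δ₃ = (start + δ₅ + |r|) − end.
5' extensions must be templated by the hairpin; a suffix of the 3' extension
that mismatches the hairpin (or runs past it) is a non-templated tail t with
|t| ≤ min(max_tail, max(δ₃, 0)). Remaining mismatches are substitutions.
Among all placements with |δ₅| ≤ 3, |δ₃| ≤ 5, |t| ≤ 3 and ≤ 2 substitutions
(defaults), the winner minimizes

    (n_substitutions, |tail|, |δ₅| + |δ₃|)

lexicographically, with ties broken by miRNA id then δ₅, so assignment is
content-based and deterministic. Each read counts once.

## Worked example

```python
import pandas as pd
from evcargo.simulate import (SimConfig, simulate_reference, simulate_abundances,
                              simulate_reads, sample_sheet_frame)
from evcargo.assign import build_index, assign_library
from evcargo.isomir import isomir_count_table
from evcargo.quantify import (percent_of_total, group_mean, threshold_filter,
                              isomir_fraction, cumulative_top_share)
from evcargo.cluster import hierarchical_cluster, log2_transform, replicate_coherence

cfg = SimConfig(seed=42, n_mirnas=40, n_shared_core=10, n_group_specific=3,
                reads_per_sample=5000)
ref = simulate_reference(cfg)
ab = simulate_abundances(cfg, ref.matures)
reads, truth = simulate_reads(cfg, ref, ab)

index = build_index(ref.matures, ref.hairpins)
tables = []
for sample, rs in reads.items():
    t, counters = assign_library(rs, index)
    t.insert(0, "sample_id", sample)
    tables.append(t[t.mirna_id != "-"])
assigned = pd.concat(tables, ignore_index=True)

counts = assigned.groupby(["mirna_id", "sample_id"]).size().unstack(fill_value=0)
pct = percent_of_total(counts)
sheet = sample_sheet_frame(cfg)
gm = group_mean(pct, sheet)

print(f"retained miRNAs (>=0.05% in some group): {len(threshold_filter(gm, 0.05))} / {counts.shape[0]}")
print(f"mean isomiR fraction: {isomir_fraction(isomir_count_table(assigned)).mean():.3f}")
print(f"top-10 cumulative share per group:\n{cumulative_top_share(gm, 10).round(1)}")
tree = hierarchical_cluster(log2_transform(pct))
print(f"replicate coherence: {replicate_coherence(tree, sheet)}")
```

prints

```
retained miRNAs (>=0.05% in some group): 40 / 40
mean isomiR fraction: 0.287
top-10 cumulative share per group:
group1    79.9
group2    77.4
group3    82.5
group4    82.2
dtype: float64
replicate coherence: {'group1': True, 'group2': True, 'group3': True, 'group4': True}
```

Roughly 29% of assigned reads are isomiRs under the default variation
process; the ten most abundant miRNAs carry ~80% of each group's cargo in
this configuration; and both biological replicates of every simulated cell
line cluster together before joining any other sample.

A command-line interface mirrors the library
(`evcargo simulate | assign | classify | quantify | cluster | snorna |
biophys | run-all`); `run-all` drives the whole pipeline from a YAML config
and writes a manifest of SHA-256 digests, byte-identical across runs with
the same seed.

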