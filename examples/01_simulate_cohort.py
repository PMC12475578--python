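"""Simulate a four-stage multi-omic cohort with planted ground truth.

The generator emits per-sample CpG methylation tracks (beta-binomial,
coverage ~25.8), peak and gene count matrices (negative binomial), TF
motif-site sets with co-binding structure, and survival columns linked to
panel methylation — plus a registry of every planted effect.
"""

import epistage as ep

cohort = ep.simulate_cohort(seed=1)

print(f"samples:        {len(cohort.sample_sheet)} "
      f"({dict(cohort.sample_sheet['stage'].value_counts())})")
print(f"CpG sites:      {cohort.meth.n_sites}")
print(f"ATAC peaks:     {len(cohort.peaks.features)}")
print(f"genes:          {len(cohort.genes.features)}")
print(f"TF site sets:   {len(cohort.tf_sites)}")
print(f"planted effects:{len(cohort.truth.effects)} "
      f"({dict(cohort.truth.effects['target'].value_counts())})")

total = cohort.meth.total
print(f"mean coverage:  {total[total > 0].mean():.2f} reads per covered CpG")
# Each planted effect switches on at its onset stage (AIS, MIA or IAC) and
# persists, so downstream earliest-onset categorization can be scored
# against the registry.
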