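"""Assign features to mutually exclusive stage-onset categories.

A feature joins the category of the EARLIEST stage (AIS < MIA < IAC) at
which it first differs from control, with the direction seen there; later
calls are ignored.  The six {hyper,hypo} x {AIS,MIA,IAC} categories
partition the ever-significant features.
"""

import epistage as ep

# the rule itself, on explicit per-stage call vectors (AIS, MIA, IAC):
for vec in [("ns", "hyper", "hypo"), ("hypo", "hyper", "hyper"),
            ("ns", "ns", "ns")]:
    print(f"{vec} -> {ep.assign_stage_category(vec)}")

# stage-resolved DMCs on a planted cohort
cohort = ep.simulate_cohort(seed=1)
dmcs_by_cat = ep.stage_resolved_dmcs(cohort.meth, cohort.stages())
for cat in sorted(dmcs_by_cat):
    print(f"{cat:10s} {len(dmcs_by_cat[cat]):4d} srDMCs")

srdmrs = ep.srdmr_table(dmcs_by_cat)
print(f"srDMRs: {len(srdmrs)} across "
      f"{srdmrs['category'].nunique()} categories")
# Each planted methylation region appears once, in the category matching
# its planted onset stage and direction.
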