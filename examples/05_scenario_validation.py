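"""Best/worst-case scenario analysis of the published validation tables.

When an algorithm flags patients who have no record in the reference
system, its true performance is only bounded: the worst case counts every
unlinked flagged patient as a false positive, the best case as a true
positive treated elsewhere.  This reproduces the published metrics of three
RA algorithms over 475,580 adults from the shipped 3x3 linkage tables.
"""

from codephen import cohort_arithmetic, compare_algorithms, scenario_analysis
from codephen.published import DATA_DRIVEN_TABLE, PUBLISHED_TABLES
from codephen.validation import format_percent as pct

report = compare_algorithms(PUBLISHED_TABLES)
print(report.to_string(index=False, float_format=lambda v: f"{100 * v:.1f}%"))

sm = scenario_analysis(DATA_DRIVEN_TABLE)
ca = cohort_arithmetic(DATA_DRIVEN_TABLE)
print(f"\ndata-driven algorithm, 475,580-adult cohort:")
print(f"  flagged RA:            {ca.flagged} ({pct(ca.flagged_fraction)})")
print(f"  of those linked:       {pct(ca.linked_fraction, 0)}")
print(f"  of linked, confirmed:  {pct(ca.confirmed_fraction, 0)}")
print(f"  worst-case prevalence: {pct(ca.prevalence_worst, 2)}")
print(f"  PPV bounds:            {pct(sm.worst.ppv)} (worst) .. {pct(sm.best.ppv)} (best)")
# The spread between the scenarios is the price of incomplete linkage: the
# latent PPV is guaranteed to lie between the two bounds.
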