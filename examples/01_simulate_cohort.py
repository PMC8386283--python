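"""Generate a synthetic case/control trio cohort with planted ground truth.

Builds a cohort at the reference study's scale (13 case vs. 19 control
trios), writes per-trio VCFs + pedigree + panel + truth table to disk, and
prints what was planted.
"""

from collections import Counter
from pathlib import Path

from trioburden import simulate_cohort, study_scale_config

out = Path("scratch_example_cohort")
cohort = simulate_cohort(study_scale_config(seed=7), out_dir=out)

n_case = len(cohort.case_trios())
n_ctrl = len(cohort.control_trios())
print(f"cohort: {n_case} case + {n_ctrl} control trios -> {out}/")

by_class = Counter(t.planted_class for t in cohort.truth if t.should_pass_filter)
decoys = sum(not t.should_pass_filter for t in cohort.truth)
print("planted filter-passing events:", dict(by_class))
print(f"decoy plants violating one filter criterion: {decoys}")
# Each truth row records the trio, site, gene, event class and whether the
# five-criterion candidate filter should keep it - the pipeline's answers
# can be scored exactly against this table.
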