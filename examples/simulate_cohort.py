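"""Generate a virtual renal-transplant cohort and summarise its exposure.

Builds a cohort with the clinical study design (51 early + 48 stable
subjects, twice-daily MMF, 10 samples over the day-4 dosing interval),
then runs non-compartmental analysis on every subject and compares
dose-normalised exposure between the post-transplant stages.
"""

import numpy as np

from mpapk import CohortDesign, PopulationModel, generate_cohort
from mpapk.nca import nca_table

model = PopulationModel.renal_transplant()
cohort = generate_cohort(model, CohortDesign(), seed=1)
print(f"cohort: {len(cohort)} subjects, {cohort.n_observations()} observations")

table = nca_table(cohort)
for stage, label in ((0, "early"), (1, "stable")):
    block = table[table.stage == stage]
    print(f"{label:>6}: AUCss,12h {block.auc_ss_12h.mean():6.1f} mg*h/L   "
          f"Cmax {block.cmax.mean():5.2f} mg/L   "
          f"AUC/dose {block.auc_per_gram.mean():6.1f} mg*h/L per g")

ratio = (table[table.stage == 1].auc_per_gram.mean()
         / table[table.stage == 0].auc_per_gram.mean())
print(f"stable/early dose-normalised exposure ratio: {ratio:.2f} "
      f"(clearance ratio exp(0.82) = {np.exp(0.82):.2f})")
# The stable stage clears MPA roughly half as fast, so the same dose
# produces about twice the exposure — the motivation for stage-specific
# dosing.
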