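"""Goodness-of-fit diagnostics: residuals and the pc-VPC.

Computes conditional weighted residuals (CWRES) and a prediction-corrected
visual predictive check for the published model on a cohort simulated from
it — the self-consistency case, where residuals should be calibrated and
~90% of observations should fall inside the simulated 5th-95th band.
"""

from mpapk import CohortDesign, PopulationModel, generate_cohort
from mpapk import _engine
from mpapk.estimation import FitOptions, FitResult, _Structure
from mpapk.evaluation import pc_vpc, residual_table

model = PopulationModel.renal_transplant()
cohort = generate_cohort(model, CohortDesign(), seed=31)

# empirical Bayes etas at the published model (no refit needed here)
packed = _engine.pack_dataset(cohort, "discard")
structure = _Structure(model, packed, FitOptions())
typ, omega2, sigma = structure.expand(structure.pack(model)[None])
etas, _, _, _ = _engine.map_etas_best(typ, omega2, sigma, packed,
                                      starts=[None], max_iter=150)
fit = FitResult(model=model, ofv=float("nan"), etas=etas[0],
                subject_ids=packed.subject_ids, shrinkage={})

table = residual_table(fit, cohort).frame
print(f"CWRES over {len(table)} observations: "
      f"mean {table.cwres.mean():+.3f}, variance {table.cwres.var():.3f} "
      f"(calibrated: ~0 and ~1)")

bands = pc_vpc(fit, cohort, n_sim=500, seed=7)
print(f"pc-VPC: {100 * bands.coverage:.1f}% of prediction-corrected "
      f"observations inside the simulated 5th-95th band")
print(bands.table().to_string(index=False, float_format=lambda v: f"{v:.2f}"))
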