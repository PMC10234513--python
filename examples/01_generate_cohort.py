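"""Generate a synthetic visit cohort and inspect its structure.

The generator draws per-patient visit sequences from a first-order Markov
chain over cost types, geometric gaps between visits, and lognormal visit
costs. Patients are then partitioned into the short-follow-up cohort D1
(< 365 days) and the long-follow-up cohort D2 (>= 365 days).
"""

import numpy as np

from osacost import SyntheticConfig, assign_cohorts, generate_cohort

config = SyntheticConfig(
    n_patients=500,
    short_followup_fraction=0.7,
    n_cost_types=12,
    visit_rate=12.0,          # expected visits per follow-up year
    max_followup_years=3.0,
    seed=42,
)
patients, truth = generate_cohort(config)

d1, d2 = assign_cohorts(patients)
print(f"patients: {len(patients)}  |D1| = {len(d1)}  |D2| = {len(d2)}")

visits_per_patient = [p.s_i for p in patients]
print(f"visits per patient: median {int(np.median(visits_per_patient))}, "
      f"max {max(visits_per_patient)}")

p = d2.patients[0]
print(f"\nfirst D2 patient {p.patient_id}: follow-up {p.t_i} days")
for v in p.visits[:6]:
    print(f"  day {v.diff_dgn:4d}  type {v.cost_type}  {v.cost_eur:7.2f} EUR")

print("\ngenerator ground truth (hidden from the models):")
print(f"  cost types: {', '.join(truth.cost_type_names)}")
print(f"  transition matrix row sums: "
      f"{np.round(truth.transition_matrix.sum(axis=1), 6)}")
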