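"""The two input/target windowings used by the models.

A patient's time axis is diff_dgn: days since their first OSA diagnosis.
The augmentation model M1 learns to continue a visit sequence, so its
targets are simply a patient's last two visits.  The cost model M2
predicts the final follow-up year, so its window boundary is the cutoff
t_i - 364: the last visit day strictly before the cutoff is t' and the
first visit day at or after it is t''.
"""

from osacost import (
    PatientHistory,
    VisitRecord,
    split_for_augmentation,
    split_for_prediction,
)


def patient_with_days(days):
    visits = [
        VisitRecord("demo", d, age=55, gender="F", specialist_type="S0",
                    cost_type="A", cost_eur=50.0)
        for d in days
    ]
    return PatientHistory("demo", visits)


# the eight-visit reference example
patient = patient_with_days([0, 30, 70, 248, 690, 810, 1100, 1140])
print(f"follow-up t_i = {patient.t_i} days, cutoff t_i - 364 = {patient.t_i - 364}")

pred = split_for_prediction(patient)
print(f"prediction split: t' = {pred.t_prime}, t'' = {pred.t_double_prime}")
print(f"  input days:  {[v.diff_dgn for v in pred.input_visits]}")
print(f"  target days: {[v.diff_dgn for v in pred.target_visits]}")

aug = split_for_augmentation(patient)
print(f"\naugmentation split (last two visits are the targets):")
print(f"  input days:  {[v.diff_dgn for v in aug.input_visits]}")
print(f"  target days: {[v.diff_dgn for v in aug.target_visits]}")
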