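"""Time-to-relapse prediction in the ovarian setting.

Generates a synthetic cohort emulating the 20-patient table structure
(age, initial burden, first-cycle volume change, observed relapse
time), fits the chemotherapy kill rate per patient, and compares three
predictors of time-to-relapse: the mechanistic sweep alone, the
age-conditioned KDE alone, and their fusion.
"""

from tumorfuse.ovarian import ovarian_pipeline, synth_ovarian_table

table = synth_ovarian_table(n_patients=20, seed=2)
result = ovarian_pipeline(table)

lo, hi = result["delta0_range"]
print(f"fitted kill-rate range for the model sweep: "
      f"{lo:.3f} - {hi:.3f} per day")
print(f"MSE (months^2) of the three predictors over {len(table)} patients:")
print(f"  mechanistic model alone: {result['mse_model']:7.3f}")
print(f"  age-KDE alone:           {result['mse_data']:7.3f}")
print(f"  fused:                   {result['mse_fused']:7.3f}")
print("\nThe fused predictor combines the burden/kill-rate information in "
      "the model with the age association in the data; at this cohort "
      "size it usually, though not always, beats both single sources.")
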