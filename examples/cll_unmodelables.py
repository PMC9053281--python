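"""Effect of adding unmodelable variables in the leukemia setting.

Generates a synthetic B-CLL cohort (labeled-fraction-at-day-50 outcome
plus four unmodelables with planted associations), then fuses the
two-compartment model's f50 histogram prior with KDE densities built
from progressively more unmodelables, and prints the prediction MSE at
each step.
"""

from tumorfuse.cll import incremental_unmodelable_mse, synth_cll_table

table = synth_cll_table(n_patients=100, seed=3)
series = incremental_unmodelable_mse(table)

print("patients:", len(table))
print("MSE of fused f50 predictions vs number of unmodelables used:")
for k, value in series.items():
    print(f"  {k} unmodelables: MSE = {value:.5f}")
print("\nEach added informative unmodelable (CD38, age, WBC growth rate, "
      "V_H status) sharpens the data density and lowers the error.")
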