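"""Phenotype prediction on the built-in toy network.

Builds the toy fermentation model, predicts the wild type and a respiration
double-knockout with FBA and MiMBl, and computes the mutant's yield space
and growth-coupling strength.
"""

import evostrain as es
from evostrain.fixtures import TOY_RATES

model, reference = es.make_toy_model()

wt = es.predict_fba(model, TOY_RATES)
print(f"wild type (FBA):    mu = {wt.mu:.2f} 1/h, vP = {wt.vP:.2f}, "
      f"vS = {wt.vS:.2f}, BPCY = {es.bpcy(wt):.3f} mol/mol/h")

mutant = model.knock_out(["RESP1", "RESP2"])
ko_fba = es.predict_fba(mutant, TOY_RATES)
ko_mimbl = es.mimbl_predict(mutant, reference, TOY_RATES)
print(f"dRESP1 dRESP2 (FBA):   mu = {ko_fba.mu:.2f}, vP = {ko_fba.vP:.2f}, "
      f"BPCY = {es.bpcy(ko_fba):.3f}")
print(f"dRESP1 dRESP2 (MiMBl): mu = {ko_mimbl.mu:.2f}, vP = {ko_mimbl.vP:.2f}, "
      f"BPCY = {es.bpcy(ko_mimbl):.3f}, turnover distance = "
      f"{ko_mimbl.objective_value:.2f}")

ys = es.yield_space(mutant, TOY_RATES)
print(f"mutant growth-coupling strength (GCS) = {es.gcs(ys):.3f}")
print("-> knocking out both respiration isozymes forces NADH reoxidation "
      "through the product branch: production becomes growth-coupled and "
      "BPCY nearly triples.")
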