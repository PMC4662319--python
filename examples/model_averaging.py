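"""Multimodel inference: which detection model do the data support?

Fits four closed-population models (constant detection vs behavioral
response, each with shared or type-specific encounter probabilities) to one
simulated dataset and combines them by reversible-jump MCMC from the saved
outputs, reporting posterior model probabilities and the model-averaged
abundance.
"""

from latentmark import SimConfig, fit_closed, process_data, simdata_closed
from latentmark.multimodel import closed_model_entry, model_average, summarize_mm

sim = simdata_closed(
    SimConfig(N=60, noccas=5, pbeta=-0.8, delta_1=0.4, delta_2=0.4,
              alpha=0.0, data_type="never"), seed=3)
setup = process_data(sim.observed_matrix, "never")

entries = []
for i, (mp, md) in enumerate(
    [("~1", "~1"), ("~1", "~type"), ("~c", "~1"), ("~c", "~type")]
):
    fit = fit_closed(setup, mod_p=mp, mod_delta=md, iter=8000, burnin=2000,
                     seed=10 + i, parms="all")
    entries.append(closed_model_entry(fit, setup))

result = model_average(entries, monparms=("N",), iter=20000, seed=99)
print("posterior model probabilities (sum to 1):")
for label, prob in sorted(result.pos_prob.items(), key=lambda kv: -kv[1]):
    print(f"   {label:24s} {prob:.3f}")
print(summarize_mm(result).round(1))
print("the truth is constant detection with delta_1 = delta_2, so the")
print("p(~1)delta(~1) model should carry the largest weight; the N row is")
print("the model-averaged abundance (mode and 95% HPDI)")
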