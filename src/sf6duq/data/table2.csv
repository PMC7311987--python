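method,quantity,estimate,se,variance
psa,mean_health_utility,0.576,0.001689017,0.000002853
psa,usual_estimate_of_uncertainty,,0.000353456,0.000000125
psa,uncertainty_due_to_value_set,,0.001651620,0.000002728
psa,total,,,0.000002853
bayesian,mean_health_utility,0.589,0.01284,0.000164866
bayesian,usual_estimate_of_uncertainty,,0.001778340,0.000003162
bayesian,uncertainty_due_to_value_set,,0.012716254,0.000161703
bayesian,total,,,0.000164866
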