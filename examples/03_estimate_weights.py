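"""Parameter recovery: estimate the heat-coefficient weights from data.

Generates a synthetic estimation cohort (8 subjects x 5 speeds) whose
measured average MEE rates come from the model with the published weights
and no noise, fits the ten weight parameters by constrained nonlinear
least squares, and validates the completed model on held-out subjects.
"""

import numpy as np

import gaitcost as gc

config = gc.GeneratorConfig(seed=11, mee_noise_sd=0.0, stride_jitter=0.0,
                            samples_per_stride=50, n_shared_validation=0)
estimation, validation, truth = gc.generate_dataset(config)
print(f"estimation: {estimation.n_strides} strides from "
      f"{len(estimation.subjects())} subjects; validation: "
      f"{len(validation.subjects())} held-out subjects")

result = gc.estimate_weights(estimation, gc.EstimationOptions(multistart=4))
print(f"objective at optimum  : {result.objective_value:.3e} W^2")
print(f"worst constraint margin: {result.constraint_report.worst:.2e}")

stats = gc.validate(result.weights, validation)
print(f"held-out mean |error| : {stats['mean_abs_pct_error']:.4f} %")
print(f"inter-subject R^2     : {stats['inter_subject_r2']:.6f}")
print()
print("With noiseless measurements the estimator drives the objective to "
      "zero and the fitted model reproduces held-out subjects' average "
      "metabolic rates essentially exactly; the weight vector itself need "
      "not equal the generating one (the model is overparameterized), but "
      "its predictions do.")
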