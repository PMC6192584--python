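"""Can the mixing model recover known diet proportions?

Simulates consumers from the model's own generative distribution with known
truth p = (0.7, 0.3) and well-separated sources, refits each one, and scores
bias, RMSE and 95% credible-interval coverage.
"""

import numpy as np

from ventmix import (
    IsotopeSummary,
    SimulationScenario,
    SourcePool,
    TDFSet,
    recovery_experiment,
)


def pool(name, c, n, sd=0.3):
    return SourcePool(name, {
        "C13": IsotopeSummary("C13", c, sd, 2),
        "N15": IsotopeSummary("N15", n, sd, 2),
    })


scenario = SimulationScenario(
    sources=[pool("near", -15.0, 5.0), pool("far", -20.0, 0.0)],
    true_proportions=[0.7, 0.3],
    tdf=TDFSet("grazer", {"C13": 0.0, "N15": 0.0}, {"C13": 0.3, "N15": 0.3}),
    n_consumers=30,
    seed=11,
)
report = recovery_experiment(scenario, iterations=40_000, seed=12)

for k, name in enumerate(report.source_names):
    print(f"{name}: truth {report.true_proportions[0, k]:.2f}  "
          f"mean estimate {report.posterior_means[:, k].mean():.3f}  "
          f"bias {report.bias[k]:+.3f}  rmse {report.rmse[k]:.3f}  "
          f"95% CI coverage {report.coverage[k]:.2f}")

print("\nSmall bias and coverage near 0.95 mean the sampler is calibrated: "
      "credible intervals can be read as frequentist confidence statements "
      "under the model's own assumptions.")
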