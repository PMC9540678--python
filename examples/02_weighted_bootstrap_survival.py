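"""Carrying label-set uncertainty into stratified survival estimates.

Compares standard practice (argmax labels, one pass) with the weighted
labeling bootstrap (resample the validation cohort, draw one label per
resampled observation from its conformal label set) on the same
simulated cohort, looking at the 90-day survival of each class stratum.
"""

import numpy as np

from labelsurv import (
    default_config,
    make_replicate,
    run_standard_practice,
    run_weighted_bootstrap,
    summarize_bootstrap,
)
from labelsurv.study import _conformal_pipeline, _naive_pipeline

config = default_config()
rep = make_replicate(scenario=2, config=config, seed=11)

thresholds, val_probs, _ = _conformal_pipeline(rep, 0.10, "multinomial_logit", seed=11)
naive_probs = _naive_pipeline(rep, "multinomial_logit")

sp = run_standard_practice(rep.validation, naive_probs)
print("standard practice (argmax labels), 90-day survival by predicted class:")
surv = sp["survival"]
for _, r in surv[surv.quantity == "surv90"].iterrows():
    print(
        f"  class {int(r.stratum)}: {r.value:.3f}  "
        f"(Greenwood 95% CI {r.ci_low:.3f}-{r.ci_high:.3f})"
    )

run = run_weighted_bootstrap(rep.validation, val_probs, thresholds, n_boot=200, seed=11)
summary = summarize_bootstrap(run)
print("\nweighted labeling bootstrap (200 resamples), same quantity:")
sub = summary[summary.quantity == "surv90"]
for _, r in sub.iterrows():
    print(
        f"  class {int(r.stratum)}: {r['mean']:.3f}  "
        f"(percentile 95% CI {r.ci_low:.3f}-{r.ci_high:.3f})"
    )

bias = sp["bias"]
print("\nstandard-practice bias vs observed-class strata (percentage points):")
for _, r in bias[bias.quantity == "surv90_pp"].iterrows():
    print(f"  class {int(r.stratum)}: {r.bias:+.1f} pp")
print(
    "\nThe bootstrap intervals widen where label sets are ambiguous, "
    "reflecting uncertainty the single-pass analysis silently ignores."
)
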