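"""Validate the pipeline end-to-end on synthetic data with known ground truth.

Generates 500 records where BUD falls 10 days per LogP unit (plus excipient,
temperature and content effects and 5 days of noise), retrains the
regressor, and checks that it recovers the injected structure.
"""

import json

from budcast import GroundTruthSpec, recovery_report

truth = GroundTruthSpec(logp_effect=-10.0, noise_sd=5.0)
report = recovery_report(truth, n_records=500, seed=0)
print(json.dumps({k: (round(v, 3) if isinstance(v, float) else v) for k, v in report.items()},
                 indent=2))
# holdout_r2 >= 0.8 and a negative logp_pred_correlation mean the model
# recovered the dominant injected LogP effect; excipient_offset_rank_corr
# near 1 means the per-excipient stabilization ranking was recovered too.
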