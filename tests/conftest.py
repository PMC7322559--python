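"""Shared fixtures, including the seeded neurovascular recovery study.

The recovery study is expensive (dozens of model inversions) and feeds two
independent checks — family-level recovery with credible-interval coverage,
and model-level recovery — so it runs once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm

import nvcdcm as nd
from nvcdcm import nvc

#: reduced four-model space used by the recovery studies: presynaptic vs
#: postsynaptic parameterisation crossed with direct vs delayed coupling,
#: shared weights, local drives only
REDUCED_SPECS = [
    nvc.NVCModelSpec("pre", "exclude", False, "direct"),
    nvc.NVCModelSpec("post", "na", False, "direct"),
    nvc.NVCModelSpec("pre", "exclude", False, "delay"),
    nvc.NVCModelSpec("post", "na", False, "delay"),
]

Q1_PARTITION = {"pre": [0, 2], "post": [1, 3]}
Q4_PARTITION = {"direct": [0, 1], "delay": [2, 3]}


@pytest.fixture(scope="session")
def schedule():
    """Reduced-length oddball schedule (about 2.7 min of fMRI at TR 2 s)."""
    return nd.generate_schedule(n_blocks=16, tones_per_block=12,
                                tone_interval=0.6, seed=11)


@pytest.fixture(scope="session")
def truth():
    return nd.default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def recovery_study(schedule):
    """Twenty seeded replicates of BOLD simulation + four-model inversion.

    Each replicate generates data from one model of the reduced space
    (cycled), fits all four candidates, and records the free energies, the
    family posteriors for the parameterisation and form factors, and the 90%
    credible-interval coverage of the coupling weights under the generating
    model's fit.
    """
    records = []
    for r in range(20):
        m = r % 4
        gen_spec = REDUCED_SPECS[m]
        truth = nd.default_ground_truth(seed=0, nvc_spec=gen_spec)
        bold, _, _ = nd.simulate_bold_dataset(truth, schedule, snr=10,
                                              seed=100 + r)
        templates = {
            "pre": nd.synthetic.drive_templates(truth, signal_type="pre"),
            "post": nd.synthetic.drive_templates(truth, signal_type="post"),
        }
        fits = nd.fit_model_space(bold, templates, schedule, REDUCED_SPECS,
                                  max_iter=48)
        F = np.array([f.free_energy for f in fits])
        q1 = nd.family_posterior(F, Q1_PARTITION)
        q4 = nd.family_posterior(F, Q4_PARTITION)
        beta_mean, beta_cov = fits[m].beta_posterior()
        sd = np.sqrt(np.diag(beta_cov))
        z = norm.ppf(0.95)
        beta_true = truth.nvc_params.beta.ravel()
        covered = ((beta_true >= beta_mean - z * sd)
                   & (beta_true <= beta_mean + z * sd))
        records.append({
            "generating_model": m,
            "generating_spec": gen_spec,
            "free_energies": F,
            "q1": q1,
            "q4": q4,
            "beta_covered": covered,
        })
    return records
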