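"""Shared synthetic-data builders for the screening tests."""

import math

import numpy as np

from ebdose import LongTable


def screen_table(seed, effect=0.3, n=200, m=3, kind="alpha"):
    """Synthetic variant-screen data.

    ``kind='alpha'``: the variant shifts the patient intercept (true signal;
    its effect folds into the between-patient variance when omitted).
    ``kind='null'``: the variant column is pure noise.
    ``kind='eps'``: a within-patient artifact column that inflates the error
    term — significant but not a patient-level signal.
    """
    rng = np.random.default_rng(seed)
    G = rng.binomial(1, 0.5, n).astype(float)
    smoke = rng.binomial(1, 0.5, n).astype(float)
    doses = np.exp(rng.uniform(math.log(0.5), math.log(8.0), (n, m)))
    base_log = 1.0 + 0.3 * smoke[:, None] + np.log(doses)
    eps = rng.normal(0.0, 0.2, (n, m))
    if kind == "alpha":
        alpha_dev = rng.normal(0.0, 0.2, n)
        logy = base_log + (effect * G + alpha_dev)[:, None] + eps
        variant = np.repeat(G, m)
        tv = ()
    elif kind == "null":
        alpha_dev = rng.normal(0.0, 0.25, n)
        logy = base_log + alpha_dev[:, None] + eps
        variant = np.repeat(G, m)
        tv = ()
    elif kind == "eps":
        z = rng.binomial(1, 0.5, (n, m)).astype(float)
        alpha_dev = rng.normal(0.0, 0.2, n)
        logy = base_log + alpha_dev[:, None] + effect * z + eps
        variant = z.reshape(-1)
        tv = ("variant",)
    else:
        raise ValueError(kind)
    return LongTable(
        np.repeat([f"p{i}" for i in range(n)], m),
        doses.reshape(-1),
        np.exp(logy).reshape(-1),
        np.column_stack([np.repeat(smoke, m), variant]),
        ("smoker", "variant"),
        time_varying_ok=tv,
    )
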