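import numpy as np
import pandas as pd

import forceallometry as fa


def point_fit(draws, scope="among"):
    """Wrap an array of slope draws in a minimal AllometryFit."""
    draws = np.asarray(draws, dtype=float)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    summary = pd.DataFrame(
        {"b": dict(mean=float(draws.mean()), ci_low=float(lo),
                   ci_high=float(hi))}).T
    return fa.AllometryFit(
        posterior_b=draws, posterior_a=np.zeros_like(draws),
        posterior_lambda=None, posterior_sds={}, summary=summary,
        diagnostics={}, scope=scope)
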