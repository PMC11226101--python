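"""Norming constants and convergence of block maxima to the limit laws.

The maximum of n i.i.d. draws has CDF F**n exactly.  Normalised with
(a_n, b_n) = (1, ln n) an exponential population converges to the standard
Gumbel; with (n**(1/alpha), 0) a Pareto(alpha) population converges to the
standard Frechet.  Here the distance to the limit is measured exactly as
sup |F**n(a_n x + b_n) - G(x)| on a fine grid.
"""

import numpy as np
from scipy import stats

from spikevt import frechet_cdf, gumbel_cdf, max_distribution_cdf, norming_constants

alpha = 20.0
pareto_cdf = lambda x: np.where(x >= 1.0, 1.0 - np.abs(x) ** -alpha, 0.0)

print("n      exp->Gumbel    Pareto(20)->Frechet")
for n in (10, 100, 1000):
    nc_e = norming_constants("exponential", n)
    grid = np.linspace(-3, 15, 20001)
    d_e = np.max(np.abs(max_distribution_cdf(stats.expon.cdf, n,
                                             nc_e.a_n * grid + nc_e.b_n)
                        - gumbel_cdf(grid)))
    nc_p = norming_constants("pareto", n, alpha=alpha)
    grid_p = np.linspace(0.5, 3.0, 20001)
    d_p = np.max(np.abs(max_distribution_cdf(pareto_cdf, n, nc_p.a_n * grid_p)
                        - frechet_cdf(grid_p, alpha)))
    print(f"{n:<6d} {d_e:<14.5f} {d_p:.5f}")

print("\nBoth distances shrink ~1/n: the normalised maxima converge to their "
      "extreme-value limit laws.")
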