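"""Frozen constants of the synthetic data generating processes (v1).

The exact numeric settings used by the originating simulation studies are
not published; the values here are this package's own declared substitutes,
chosen so that both correlations and variances vary visibly with the
covariates while every generated covariance matrix stays positive-definite.
They are versioned: changing any value is a breaking change for seeded
reproducibility.
"""

import numpy as np

DGP_CONSTANTS_VERSION = 1

# DGP1/DGP2: Sigma_x = PSI + B u u' B' with u = (1, x)' (DGP2: (1, x + x^2)').
# Rows of B are distinct and nonzero so the induced correlation moves from
# about -0.25 at x = 1 to +0.32 at x = 0 and variances span [1.0, 4.6].
DGP12_PSI = np.eye(2)
DGP12_B = np.array([[1.0, 0.9], [0.5, -0.8]])

# DGP3: depth-3 binary tree on (X1, ..., X7), thresholds all at 0.
# Leaf order: (X1<=0, X2<=0, X4<=0), (X1<=0, X2<=0, X4>0), (X1<=0, X2>0,
# X5<=0), ..., (X1>0, X3>0, X7>0).  All eight base correlations distinct.
DGP3_LEAF_RHO = np.array([0.90, 0.775, 0.65, 0.525, 0.40, 0.275, 0.15, 0.05])

# DGP4: rho_i = expit(b0 + sum_k b_k X_ik); coefficient magnitudes decrease
# so X1 has the strongest effect and X3 the weakest.
DGP4_BETA0 = 0.0
DGP4_BETA = np.array([2.0, 1.0, 0.5])
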