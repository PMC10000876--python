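"""Outline morphometrics end to end: simulate two cohorts of first-molar
crown outlines, build the Fourier morphospace and test for a cohort
difference.

The mutant cohort carries a 0.3-radian linguo-distal shift of its first
cusp. The pipeline resamples each outline to 64 equally spaced points,
computes 9 elliptic Fourier harmonics, normalizes them for size,
orientation and start point, runs a covariance PCA, retains the axes
covering 95% of variance, rank-transforms the retained coordinates and
applies a two-group Wilks MANOVA.
"""

from odontomorph.morphospace import outline_pipeline
from odontomorph.simulate import OutlineModelParams, simulate_outline_cohorts

params = OutlineModelParams(delta_theta_c1=0.3)
outlines = simulate_outline_cohorts(params, n_wt=21, n_mut=33, seed=1)
result = outline_pipeline(outlines)

m = result.manova
print(f"specimens: {len(result.matrix.X)}  shape variables: {result.matrix.n_variables}")
print(f"axes retained (95% variance): {result.n_axes_retained}")
print(f"Wilks lambda = {m.wilks_lambda:.3f}  F = {m.f_statistic:.3f} "
      f"(df {m.df1}/{m.df2})  p = {m.p_value:.2e}")
print(f"most discriminant axis: PC{result.extreme_axis + 1}")
# A small lambda / large F with p << 0.05 means the two cohorts occupy
# measurably different regions of the outline morphospace, driven here by
# the injected cusp shift.
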