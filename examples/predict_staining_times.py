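"""Predict optimal staining times from published fitted constants.

Uses the fitted staining-time model t_stain = A·exp(c·x) for 90%
saturation with I2KI, and the front-propagation asymptotes for PTA/PMA,
to answer the practical question: how long must a ligament sample of a
given radius sit in the stain, and can the stain reach its centre at all?
"""

from ctstain import (
    FrontModel,
    SaturationFit,
    StainTimeModel,
    max_penetration_depth,
    predict_staining_time,
    saturation_fraction,
)

m90 = StainTimeModel(A=1.007, c=0.313, saturation_level=0.90)
for depth in (1.5, 3.0):
    t = predict_staining_time(m90, depth)
    print(f"I2KI, 90% saturation at {depth:.1f} mm depth: {t:.1f} days")
# 1.6 and 2.6 days: staining time grows exponentially with depth.

for stain, (i0, imax, k) in {
    "I2KI": (0.065, 0.357, 1.108),
    "PTA": (0.068, 0.648, 0.489),
    "PMA": (0.073, 0.401, 0.920),
}.items():
    fit = SaturationFit(I0=i0, Imax=imax, k=k)
    pct = 100 * saturation_fraction(fit, 4.0)
    print(f"{stain}: {pct:.0f}% of Imax reached after 4 days of staining")
# I2KI and PMA are nearly saturated by day 4; PTA (k = 0.489/day) is not.

for stain, (C, K) in {"PTA": (3.094, 0.367), "PMA": (2.056, 0.607)}.items():
    m = FrontModel(C=C, K=K)
    print(f"{stain}: stain front never penetrates deeper than "
          f"{max_penetration_depth(m):.1f} mm — samples with a larger "
          f"radius cannot be stained through")
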