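"""Gender-adjusted regressions of clinical strength and expression on age.

A clinical table of MRC muscle-strength scores (0-5 scale) declining with
age is fitted per muscle, and a noiseless expression-vs-age course is
fitted with quadratic and two-segment linear models around the 42.5-year
breakpoint that separates young from mid-life+ subjects.
"""

import numpy as np

import myoaging as ma

clinical = ma.generate_clinical_table(
    33,
    true_beta_per_muscle={"iliopsoas": -0.07, "biceps": -0.03, "deltoid": 0.0},
    noise_sd=0.3,
    seed=5,
)
print("clinical slopes (MRC units per year, gender-adjusted):")
print(ma.fit_clinical_slopes(clinical).round(4).to_string())

ages = np.linspace(17, 89, 75)
level = 1.0 - 0.006 * (42.5 - 17)
fold_change = np.where(ages <= 42.5, 1.0 - 0.006 * (ages - 17),
                       level - 0.029 * (ages - 42.5))
pw = ma.fit_age_trend(fold_change, ages, model="piecewise", breakpoint=42.5)
print(f"\npiecewise expression fit: slope {pw.segments[0].beta('age'):+.4f}/y below "
      f"{pw.breakpoint} y, {pw.segments[1].beta('age'):+.4f}/y above")
quad = ma.fit_age_trend(fold_change, ages, model="quadratic")
print(f"quadratic fit: age {quad.beta('age'):+.5f}, age^2 {quad.beta('age_sq'):+.6f}")
# the decline concentrates after the breakpoint: flat-ish young segment,
# clear negative slope in the older segment
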