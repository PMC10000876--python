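"""Tabulate discrete crown-trait frequencies from the packaged upper-molar
survey (33 Jagged1-mutant and 21 wild-type mice, both sides scored).

Each frequency counts tooth sides showing the variant state among all
scored sides of the cohort; sides recorded as missing are excluded from
the denominator.
"""

from odontomorph.crownstats import morphotype_frequencies
from odontomorph.dataio import load_upper_molar_survey

survey = load_upper_molar_survey()

for trait, state, label in (
    ("m1_c1c2_profile", "U", "M1 low U-shaped c1-c2 profile"),
    ("m2_spur", "absent", "M2 c1 spur absent"),
    ("m3_c1", "reduced", "M3 c1 reduced"),
):
    rep = morphotype_frequencies(survey, "mutant", trait, state)
    print(f"mutant {label}: {rep.count_observed}/{rep.count_scored} "
          f"= {rep.percentage:.1f}%")

wt = morphotype_frequencies(survey, "WT", "m1_c1c2_profile", "U")
print(f"WT M1 U-shaped profile: {wt.count_observed}/{wt.count_scored} "
      f"= {wt.percentage:.1f}%")
# The three mutant frequencies (about 60%, 60% and 30%) are absent from the
# wild-type cohort, which shows the V-shaped profile on every scored side.
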